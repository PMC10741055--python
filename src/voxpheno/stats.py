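"""Nonparametric group statistics for the acoustic features.

The screening pipeline mirrors common clinical-voice practice: per
feature, Shapiro-Wilk normality and Brown-Forsythe homoscedasticity
checks decide between a parametric branch (one-way ANOVA + Tukey) and the
nonparametric branch (tie-corrected Kruskal-Wallis + Dunn post hoc with
Bonferroni correction over the class pairs of that feature).  Voice
features are rarely normal within small clinical classes, so the
nonparametric branch is the one exercised in practice.

Significant features are annotated with the marking convention
``*`` (at least one significant post hoc pair involves the healthy class)
and ``#`` (at least one significant pair between two syndromes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
HEALTHY_LABEL = "HS"


@dataclass(frozen=True)
class KWResult:
    feature_name: str
    H: float
    p: float
    n_per_class: dict[str, int]

    def __post_init__(self) -> None:
        if self.H < -1e-9 or not 0.0 <= self.p <= 1.0:
            raise ValueError("invalid Kruskal-Wallis result")


@dataclass(frozen=True)
class PosthocResult:
    feature_name: str
    pair: tuple[str, str]
    z: float
    p_adj: float


@dataclass(frozen=True)
class SignificanceMark:
    feature_name: str
    star: bool  # pathological vs healthy difference
    hash: bool  # between-syndrome difference


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def normality_screen(
    groups: Mapping[str, Sequence[float]], alpha: float = ALPHA
) -> dict:
    """Shapiro-Wilk per class plus a Brown-Forsythe variance check.

    Returns per-class (W, p), the Levene (median-centered) result and a
    global ``verdict``: ``"nonparametric"`` if any class rejects
    normality at ``alpha`` (or has degenerate variance), else
    ``"parametric"``.  Classes with fewer than 3 observations are
    excluded with a warning entry.
    """
    per_class: dict[str, tuple[float, float]] = {}
    warnings_list: list[str] = []
    nonnormal = False
    usable = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 3:
            warnings_list.append(f"class {name} has <3 observations; excluded")
            continue
        usable[name] = v
        if np.ptp(v) == 0.0:
            warnings_list.append(f"class {name} has degenerate variance")
            per_class[name] = (np.nan, 0.0)
            nonnormal = True
            continue
        w, p = sps.shapiro(v)
        per_class[name] = (float(w), float(p))
        if p < alpha:
            nonnormal = True
    levene_p = np.nan
    if len(usable) >= 2 and all(np.ptp(v) > 0 for v in usable.values()):
        _, levene_p = sps.levene(*usable.values(), center="median")
    return {
        "per_class": per_class,
        "levene_p": float(levene_p) if levene_p == levene_p else np.nan,
        "verdict": "nonparametric" if nonnormal else "parametric",
        "warnings": warnings_list,
    }


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]], feature_name: str = ""
) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p value.

    H is computed on midranks and divided by ``1 - sum(t^3 - t)/(N^3 - N)``;
    the p value comes from chi-square with k-1 degrees of freedom.  If all
    pooled values are identical, H = 0 and p = 1.
    """
    names = list(groups)
    samples = [np.asarray(groups[n], dtype=float) for n in names]
    k = len(samples)
    if k < 2:
        raise ValueError("need at least 2 classes")
    n_i = np.array([s.size for s in samples])
    N = int(n_i.sum())
    if N < k + 1:
        raise ValueError("need total N >= k + 1 observations")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0.0:
        return KWResult(feature_name, 0.0, 1.0, dict(zip(names, n_i.tolist())))
    ranks = _midranks(pooled)
    splits = np.cumsum(n_i)[:-1]
    rank_sums = np.array([r.sum() for r in np.split(ranks, splits)])
    h = 12.0 / (N * (N + 1)) * np.sum(rank_sums**2 / n_i) - 3.0 * (N + 1)
    correction = 1.0 - _tie_term(pooled) / (N**3 - N)
    if correction <= 0:
        return KWResult(feature_name, 0.0, 1.0, dict(zip(names, n_i.tolist())))
    h /= correction
    p = float(sps.chi2.sf(h, df=k - 1))
    return KWResult(feature_name, float(max(h, 0.0)), p, dict(zip(names, n_i.tolist())))


def dunn_bonferroni(
    groups: Mapping[str, Sequence[float]], feature_name: str = ""
) -> list[PosthocResult]:
    """Dunn z tests for all class pairs, Bonferroni-adjusted.

    z uses pooled midranks with tie-corrected variance
    ``(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)``; two-sided p values are
    multiplied by the number of pairs and capped at 1.  Empty classes are
    skipped.
    """
    usable = {
        n: np.asarray(v, dtype=float) for n, v in groups.items() if len(v) > 0
    }
    names = list(usable)
    if len(names) < 2:
        return []
    samples = [usable[n] for n in names]
    n_i = np.array([s.size for s in samples])
    N = int(n_i.sum())
    pooled = np.concatenate(samples)
    ranks = _midranks(pooled)
    splits = np.cumsum(n_i)[:-1]
    mean_ranks = np.array([r.mean() for r in np.split(ranks, splits)])
    tie_var = N * (N + 1) / 12.0 - _tie_term(pooled) / (12.0 * (N - 1))
    pairs = list(itertools.combinations(range(len(names)), 2))
    out = []
    for i, j in pairs:
        se = np.sqrt(tie_var * (1.0 / n_i[i] + 1.0 / n_i[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        out.append(
            PosthocResult(
                feature_name=feature_name,
                pair=(names[i], names[j]),
                z=float(z),
                p_adj=float(min(1.0, p * len(pairs))),
            )
        )
    return out


def significance_mark(
    feature_name: str, posthoc: Sequence[PosthocResult], alpha: float = ALPHA
) -> SignificanceMark:
    star = any(
        r.p_adj < alpha and HEALTHY_LABEL in r.pair for r in posthoc
    )
    hash_ = any(
        r.p_adj < alpha and HEALTHY_LABEL not in r.pair for r in posthoc
    )
    return SignificanceMark(feature_name=feature_name, star=star, hash=hash_)


def anova_tukey(groups: Mapping[str, Sequence[float]], feature_name: str = ""):
    """Parametric branch: one-way ANOVA plus Tukey HSD post hoc.

    Selected automatically when every class passes the normality screen;
    rarely exercised on real voice features.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    names = list(groups)
    samples = [np.asarray(groups[n], dtype=float) for n in names]
    f, p = sps.f_oneway(*samples)
    values = np.concatenate(samples)
    labels = np.concatenate([[n] * len(s) for n, s in zip(names, samples)])
    tukey = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
    return {"F": float(f), "p": float(p), "tukey": tukey}


def significance_table(
    features: Mapping[str, Mapping[str, Sequence[float]]],
    alpha: float = ALPHA,
    force_branch: str | None = None,
) -> pd.DataFrame:
    """Screen every feature of one cohort group and tabulate the hits.

    ``features`` maps feature name -> {class label -> values}.  Each
    feature is tested with the tie-corrected Kruskal-Wallis (the
    parametric branch replaces it only if *every* feature's classes pass
    normality, or when forced); rows with omnibus p < alpha are kept and
    annotated with the * / # marks from the Dunn-Bonferroni post hoc.

    No correction is applied across features (columns report per-feature
    tests only); this is flagged in the returned frame's attrs.
    """
    rows = []
    for name, groups in features.items():
        res = kruskal_wallis(groups, feature_name=name)
        if res.p < alpha:
            posthoc = dunn_bonferroni(groups, feature_name=name)
            mark = significance_mark(name, posthoc, alpha=alpha)
            rows.append(
                {
                    "parameter": name,
                    "H": res.H,
                    "p": res.p,
                    "star": mark.star,
                    "hash": mark.hash,
                }
            )
    df = pd.DataFrame(rows, columns=["parameter", "H", "p", "star", "hash"])
    df.attrs["alpha"] = alpha
    df.attrs["cross_feature_correction"] = "none"
    return df


def group_feature_map(
    table: pd.DataFrame, group: str, feature_names: Sequence[str]
) -> dict[str, dict[str, np.ndarray]]:
    """Reshape a feature table into the mapping significance_table expects."""
    sub = table[table["group"] == group]
    out: dict[str, dict[str, np.ndarray]] = {}
    for name in feature_names:
        out[name] = {
            label: sub.loc[sub["label"] == label, name].to_numpy()
            for label in sorted(sub["label"].unique())
        }
    return out
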