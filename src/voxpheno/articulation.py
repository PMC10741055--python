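"""Vowel-triangle construction and articulatory metrics.

The three cardinal vowels /a/, /I/, /u/ span a triangle in the (F2, F1)
plane whose geometry reflects articulatory range.  Reduced area (VSA)
and increased centralization (FCR) indicate restricted tongue and jaw
movement; the three formant ratios isolate vertical (F1a/F1I, F1a/F1u)
and horizontal (F2I/F2u) tongue mobility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from voxpheno.acoustics import AcousticProfile


@dataclass(frozen=True)
class VowelTriangle:
    """Mean F1/F2 coordinates of /a/, /I/ and /u/ for one subject-session."""

    F1a: float
    F2a: float
    F1I: float
    F2I: float
    F1u: float
    F2u: float

    def __post_init__(self) -> None:
        for name in ("F1a", "F2a", "F1I", "F2I", "F1u", "F2u"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_profiles(cls, profiles: Mapping[str, AcousticProfile]) -> "VowelTriangle":
        """Build from per-vowel acoustic profiles (mean formants)."""
        missing = {"a", "I", "u"} - set(profiles)
        if missing:
            raise KeyError(f"profiles missing vowels: {sorted(missing)}")
        return cls(
            F1a=profiles["a"].f1_mean,
            F2a=profiles["a"].f2_mean,
            F1I=profiles["I"].f1_mean,
            F2I=profiles["I"].f2_mean,
            F1u=profiles["u"].f1_mean,
            F2u=profiles["u"].f2_mean,
        )


@dataclass(frozen=True)
class ArticulatoryMetrics:
    """The five triangle-derived articulation measures."""

    vsa: float  # Hz^2
    fcr: float
    f_ratio_aI: float
    f_ratio_au: float
    f_ratio_Iu: float

    def as_dict(self) -> dict[str, float]:
        return {
            "vsa": self.vsa,
            "fcr": self.fcr,
            "f_ratio_aI": self.f_ratio_aI,
            "f_ratio_au": self.f_ratio_au,
            "f_ratio_Iu": self.f_ratio_Iu,
        }


ARTICULATORY_FEATURES = ("vsa", "fcr", "f_ratio_aI", "f_ratio_au", "f_ratio_Iu")


def vsa(tri: VowelTriangle) -> float:
    """Vowel space area in Hz^2.

    ``|F1I (F2a - F2u) + F1a (F2u - F2I) + F1u (F2I - F2a)| / 2`` — the
    triangle area in the (F2, F1) plane; 0 for degenerate (collinear)
    configurations.
    """
    return (
        abs(
            tri.F1I * (tri.F2a - tri.F2u)
            + tri.F1a * (tri.F2u - tri.F2I)
            + tri.F1u * (tri.F2I - tri.F2a)
        )
        / 2.0
    )


def fcr(tri: VowelTriangle) -> float:
    """Formant centralization ratio.

    ``(F2u + F2a + F1I + F1u) / (F2I + F1a)``; rises as the vowels
    centralize, and is designed to flag dysarthric articulation while
    suppressing between-speaker scale differences.
    """
    denom = tri.F2I + tri.F1a
    if denom <= 0:
        raise ZeroDivisionError("FCR denominator F2I + F1a must be positive")
    return (tri.F2u + tri.F2a + tri.F1I + tri.F1u) / denom


def f_ratios(tri: VowelTriangle) -> tuple[float, float, float]:
    """Formant ratios (F1a/F1I, F1a/F1u, F2I/F2u).

    The first two track vertical tongue movement, the third horizontal
    movement.
    """
    if min(tri.F1I, tri.F1u, tri.F2u) <= 0:
        raise ZeroDivisionError("formant-ratio denominators must be positive")
    return (tri.F1a / tri.F1I, tri.F1a / tri.F1u, tri.F2I / tri.F2u)


def articulatory_metrics(tri: VowelTriangle) -> ArticulatoryMetrics:
    r_aI, r_au, r_Iu = f_ratios(tri)
    return ArticulatoryMetrics(
        vsa=vsa(tri), fcr=fcr(tri), f_ratio_aI=r_aI, f_ratio_au=r_au, f_ratio_Iu=r_Iu
    )


#: line styling per class for triangle plots (one entry per class plus the
#: language reference triangle).
TRIANGLE_STYLES = {
    "HS": {"linestyle": "-", "marker": None},
    "SMS": {"linestyle": ":", "marker": None},
    "NS": {"linestyle": "--", "marker": "o"},
    "CS": {"linestyle": "--", "marker": None},
    "DS": {"linestyle": "-.", "marker": None},
    "reference": {"linestyle": "-", "marker": "D"},
}

#: Italian adult-male reference triangle for plotting context only (the /I/
#: F2 sits a few hundred Hz below the American English /i/).
ITALIAN_ADULT_MALE_REFERENCE = VowelTriangle(
    F1a=700.0, F2a=1250.0, F1I=300.0, F2I=1950.0, F1u=320.0, F2u=800.0
)


def triangle_plot_data(
    triangles: Mapping[str, VowelTriangle],
    include_reference: bool = False,
) -> dict[str, dict]:
    """Plot specification for a set of labeled vowel triangles.

    F2 is the abscissa, F1 the ordinate; each triangle becomes a closed
    polyline visiting /a/, /I/, /u/.  Returns a mapping
    ``label -> {"f2": [...], "f1": [...], "style": {...}}`` consumable by
    any plotting backend.
    """
    if not triangles and not include_reference:
        raise ValueError("need at least one triangle")
    items = dict(triangles)
    if include_reference:
        items["reference"] = ITALIAN_ADULT_MALE_REFERENCE
    out = {}
    for label, tri in items.items():
        out[label] = {
            "f2": [tri.F2a, tri.F2I, tri.F2u, tri.F2a],
            "f1": [tri.F1a, tri.F1I, tri.F1u, tri.F1a],
            "style": TRIANGLE_STYLES.get(label, {"linestyle": "-", "marker": None}),
        }
    return out


def plot_triangles(plot_data: dict[str, dict], path: str) -> None:
    """Render a triangle plot specification to SVG/PNG via matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for label, spec in plot_data.items():
        ax.plot(
            spec["f2"],
            spec["f1"],
            label=label,
            linestyle=spec["style"]["linestyle"],
            marker=spec["style"]["marker"],
        )
    ax.set_xlabel("F2 (Hz)")
    ax.set_ylabel("F1 (Hz)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
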