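"""Diet-category engine, skeletal body-mass regression, Youden cut-points
and the mass-based diet exclusion rules.

Diet categories are assigned from percentage-of-diet rows (EltonTraits-style
columns) against configurable thresholds; fossil masses come from a published
multivariate regression over six log10 limb measurements; guild boundaries on
log10 mass are optimised with the Youden index J = sensitivity + specificity - 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .errors import AmbiguousDietError, ClassificationError

__all__ = [
    "DIET_CATEGORIES",
    "DietProfile",
    "DietCategory",
    "SkeletalMeasures",
    "MassEstimate",
    "CutpointResult",
    "load_cutoffs",
    "preprocess_profile",
    "classify_diet",
    "enan_mass",
    "youden_cutpoints",
    "mass_rule",
    "aggregate_mass",
]

DIET_CATEGORIES = (
    "Folivore", "FrugivoreH", "FrugivoreS", "Generalist", "GranivoreH",
    "GranivoreS", "InvertivoreH", "InvertivoreM", "InvertivoreS",
    "Nectarivore", "Piscivore", "Scavenger", "TetrapodHunter",
)

_PCT_COLUMNS = ("Inv", "Ect", "End", "Vunk", "Fish", "Scav",
                "Fruit", "Nect", "Seed", "PlantO", "Tetr")

#: carnivore guild membership used by the mass exclusion rules
VERTIVORE_CATEGORIES = frozenset({"Piscivore", "Scavenger", "TetrapodHunter"})
INVERTIVORE_CATEGORIES = frozenset({"InvertivoreH", "InvertivoreM", "InvertivoreS"})
FOLFRUG_CATEGORIES = frozenset({"Folivore", "FrugivoreH", "FrugivoreS"})
GRANNECT_CATEGORIES = frozenset({"GranivoreH", "GranivoreS", "Nectarivore"})


def load_cutoffs() -> dict:
    """Threshold configuration shipped with the package (JSON, user-editable)."""
    with resources.files("avidiet.data").joinpath("diet_cutoffs.json").open() as fh:
        return json.load(fh)


@dataclass
class DietProfile:
    """Percentage-of-diet row plus the annotations needed for subcategories."""

    percentages: dict[str, float]
    fruit_hardness: str | None = None      # "hard" | "soft"
    granivory_mode: str | None = None      # "husk" | "swallow"
    invert_hardness: str | None = None     # "hard" | "medium" | "soft"
    scavenger_note: str | None = None

    def __post_init__(self):
        p = {c: float(self.percentages.get(c, 0.0)) for c in _PCT_COLUMNS}
        for c, v in p.items():
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"percentage {c}={v} outside [0, 100]")
        total = sum(p.values())
        if abs(total - 100.0) > 0.5:
            raise ValueError(f"percentages sum to {total}, expected 100 +/- 0.5")
        self.percentages = p


@dataclass(frozen=True)
class DietCategory:
    name: str
    specialist_level: str = "standard"  # "standard" | "semi"

    def __post_init__(self):
        if self.name not in DIET_CATEGORIES:
            raise ValueError(f"unknown diet category {self.name!r}")
        if self.specialist_level not in ("standard", "semi"):
            raise ValueError("specialist_level must be 'standard' or 'semi'")


def preprocess_profile(p: DietProfile) -> DietProfile:
    """Merge tetrapod columns and split the unknown-vertebrate share.

    Tetr = Ect + End (+ Vunk/2); Fish gains Vunk/2; Vunk is zeroed.
    """
    pct = dict(p.percentages)
    vunk = pct.get("Vunk", 0.0)
    pct["Tetr"] = pct.get("Tetr", 0.0) + pct.get("Ect", 0.0) + pct.get("End", 0.0) + vunk / 2.0
    pct["Fish"] = pct.get("Fish", 0.0) + vunk / 2.0
    pct["Ect"] = 0.0
    pct["End"] = 0.0
    pct["Vunk"] = 0.0
    return replace(p, percentages=pct)


def _subcategory(base: str, p: DietProfile) -> str:
    if base == "Invertivore":
        mode = {"hard": "InvertivoreH", "medium": "InvertivoreM",
                "soft": "InvertivoreS"}.get(p.invert_hardness or "")
        if mode is None:
            raise ClassificationError(
                "invertivore requires invert_hardness annotation (hardest group consumed)")
        return mode
    if base == "Frugivore":
        mode = {"hard": "FrugivoreH", "soft": "FrugivoreS"}.get(p.fruit_hardness or "")
        if mode is None:
            raise ClassificationError("frugivore requires fruit_hardness annotation")
        return mode
    if base == "Granivore":
        mode = {"husk": "GranivoreH", "swallow": "GranivoreS"}.get(p.granivory_mode or "")
        if mode is None:
            raise ClassificationError("granivore requires granivory_mode annotation")
        return mode
    return base


def classify_diet(
    p: DietProfile,
    include_semi: bool = False,
    cutoffs: dict | None = None,
) -> DietCategory | None:
    """Apply the threshold table; returns None when no rule fires.

    Standard cut-offs are tried first; when ``include_semi`` is set, semi
    cut-offs (and the relaxed generalist rule) are tried for profiles no
    standard rule matched.  Two cut-offs firing at the same level raises
    :class:`AmbiguousDietError` reporting both.
    """
    cfg = cutoffs or load_cutoffs()
    p = preprocess_profile(p)
    pct = p.percentages

    for level in ("standard",) + (("semi",) if include_semi else ()):
        hits = [name for name, rule in cfg["categories"].items()
                if pct.get(rule["column"], 0.0) >= rule[level]]
        if len(hits) > 1:
            raise AmbiguousDietError([_subcategory(h, p) for h in hits])
        if hits:
            return DietCategory(_subcategory(hits[0], p), specialist_level=level)
        gmax = cfg["generalist"]["standard_max" if level == "standard" else "semi_max"]
        if max(pct.values()) <= gmax:
            return DietCategory("Generalist", specialist_level=level)
    return None


# ---------------------------------------------------------------------------
# Body mass


#: regression coefficients over log10 skeletal measurements
ENAN_INTERCEPT = -2.626
ENAN_COEF = {"HL": 1.528, "bcL": 0.34, "dHW": 0.828,
             "UL": -1.451, "dUW": 0.811, "TL": 0.378}


@dataclass(frozen=True)
class SkeletalMeasures:
    """log10 linear measurements feeding the mass regression."""

    HL: float
    bcL: float
    dHW: float
    UL: float
    dUW: float
    TL: float
    correction: float = 1.0

    def __post_init__(self):
        vals = [self.HL, self.bcL, self.dHW, self.UL, self.dUW, self.TL]
        if not all(np.isfinite(vals)):
            raise ValueError("all six predictors must be finite")
        if self.correction <= 0:
            raise ValueError("correction factor must be positive")


@dataclass(frozen=True)
class MassEstimate:
    mean: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (0 < self.lower <= self.mean <= self.upper):
            raise ValueError(f"require 0 < lower <= mean <= upper, got {self}")


#: default symmetric log10 half-width giving mean/lower ratios ~ 1.25
DEFAULT_LOG10_HALFWIDTH = float(np.log10(1.25))


def enan_mass(
    m: SkeletalMeasures,
    log10_halfwidth: float = DEFAULT_LOG10_HALFWIDTH,
    unit_to_g: float = 1.0,
) -> MassEstimate:
    """Point mass estimate (with symmetric log-scale interval) from the regression.

    The fitted mass unit of the source regression is not restated here, so the
    conversion to grams is an explicit parameter (default: fitted units taken
    as grams).  ``log10_halfwidth`` is a caller-supplied stand-in for the
    source error model.
    """
    lp = ENAN_INTERCEPT + sum(ENAN_COEF[k] * getattr(m, k) for k in ENAN_COEF)
    mean = m.correction * 10.0 ** lp * unit_to_g
    lower = m.correction * 10.0 ** (lp - log10_halfwidth) * unit_to_g
    upper = m.correction * 10.0 ** (lp + log10_halfwidth) * unit_to_g
    return MassEstimate(mean=mean, lower=lower, upper=upper)


def aggregate_mass(
    sex_masses: list[float] | None = None,
    population_masses: list[float] | None = None,
    population_counts: list[float] | None = None,
    min_max: tuple[float, float] | None = None,
) -> float:
    """Collapse reported masses into one value: unweighted sex average,
    sample-count-weighted population average, or min/max midpoint."""
    if sex_masses:
        return float(np.mean(sex_masses))
    if population_masses:
        w = population_counts if population_counts else [1.0] * len(population_masses)
        return float(np.average(population_masses, weights=w))
    if min_max is not None:
        return 0.5 * (min_max[0] + min_max[1])
    raise ValueError("no mass information supplied")


@dataclass(frozen=True)
class CutpointResult:
    """All Youden-optimal thresholds (g) plus the attained J."""

    thresholds_g: tuple[float, ...]
    youden_j: float
    positive_is_larger: bool

    def __post_init__(self):
        if not (-1.0 <= self.youden_j <= 1.0):
            raise ValueError("J outside [-1, 1]")


def youden_cutpoints(masses_g, labels) -> CutpointResult:
    """Maximise J over midpoints between consecutive distinct log10 masses.

    ``labels`` is a binary guild indicator (any two values).  "Positive" is
    defined as the guild with the larger mean log10 mass; all tied maximisers
    are returned, sorted ascending and back-transformed to grams.
    """
    masses = np.asarray(masses_g, dtype=float)
    labs = np.asarray(labels)
    if masses.shape != labs.shape:
        raise ValueError("masses and labels must have the same length")
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    uniq = np.unique(labs)
    if len(uniq) != 2:
        raise ClassificationError(f"need exactly 2 guilds, got {list(uniq)}")
    x = np.log10(masses)
    mean0, mean1 = x[labs == uniq[0]].mean(), x[labs == uniq[1]].mean()
    pos_label = uniq[1] if mean1 >= mean0 else uniq[0]
    pos = labs == pos_label

    xs = np.unique(x)
    if len(xs) < 2:
        raise ClassificationError("all masses identical; no threshold exists")
    cands = 0.5 * (xs[:-1] + xs[1:])
    n_pos, n_neg = pos.sum(), (~pos).sum()
    best_j, best = -np.inf, []
    for t in cands:
        sens = np.sum(pos & (x > t)) / n_pos
        spec = np.sum(~pos & (x <= t)) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best = j, [t]
        elif abs(j - best_j) <= 1e-12:
            best.append(t)
    return CutpointResult(
        thresholds_g=tuple(float(10.0 ** t) for t in sorted(best)),
        youden_j=float(best_j),
        positive_is_larger=True,
    )


# ---------------------------------------------------------------------------
# Mass-based exclusion rules


#: (g) indeterminate band bounds for carnivores and herbivores
CARNIVORE_BAND = (300.0, 450.0)
HERBIVORE_BAND = (250.0, 400.0)


def mass_rule(mass: MassEstimate) -> set[str]:
    """Diet categories excluded by a mass interval.

    Entirely below the carnivore band excludes vertivory; entirely above it
    excludes invertivory.  Entirely below the herbivore band excludes
    folivory/frugivory; entirely above it excludes granivory/nectarivory.
    Intervals straddling a band exclude nothing for that comparison.
    """
    excluded: set[str] = set()
    if mass.upper < CARNIVORE_BAND[0]:
        excluded |= VERTIVORE_CATEGORIES
    if mass.lower > CARNIVORE_BAND[1]:
        excluded |= INVERTIVORE_CATEGORIES
    if mass.upper < HERBIVORE_BAND[0]:
        excluded |= FOLFRUG_CATEGORIES
    if mass.lower > HERBIVORE_BAND[1]:
        excluded |= GRANNECT_CATEGORIES
    return excluded
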