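"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is a deterministic function of its configuration and seed:
pure-birth time trees rescaled to 94 Ma, Brownian traits with additive
group effects, exact three-point claw arcs per pedal-ecology label, jaw
outlines whose depth/length aspect differs between strong- and weak-jaw
guilds, and percentage diet rows constructed to classify back to their label.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import dendropy
import numpy as np
import pandas as pd

from .diet import DIET_CATEGORIES, DietProfile, load_cutoffs
from .morphometrics import DIGITS, ClawLandmarks
from .phylo import TimeTree, PhyloCov, TraitMatrix, phylo_vcv, scale_tree_depth

__all__ = [
    "SynthConfig",
    "load_guild_config",
    "simulate_tree",
    "simulate_bm_traits",
    "synth_claws",
    "synth_jaw",
    "synth_diet_table",
    "PEDAL_LABELS",
]

PEDAL_LABELS = ("Ground", "Perch", "Restraint", "Strike", "Suffocate",
                "Pierce", "Scavenger")


def load_guild_config() -> dict:
    with resources.files("avidiet.data").joinpath("guilds.json").open() as fh:
        return json.load(fh)


@dataclass
class SynthConfig:
    """Shared knobs for the generators."""

    seed: int = 0
    n_taxa: int = 32
    birth_rate: float = 1.0
    tree_depth_ma: float = 94.0
    n_traits: int = 3
    sigma2_per_ma: float = 1.0
    group_effects: dict[str, np.ndarray] = field(default_factory=dict)
    noise_sd: float = 0.0
    n_fossils: int = 0

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if self.sigma2_per_ma <= 0 or self.birth_rate <= 0:
            raise ValueError("rates must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def simulate_tree(cfg: SynthConfig) -> TimeTree:
    """Pure-birth tree conditioned on ``n_taxa`` tips, rescaled to the target depth."""
    rng = np.random.default_rng(cfg.seed)
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    left, right = dendropy.Node(), dendropy.Node()
    root.add_child(left)
    root.add_child(right)
    tips = [left, right]
    birth_times = {left: 0.0, right: 0.0}
    t = 0.0
    while len(tips) < cfg.n_taxa:
        t += rng.exponential(1.0 / (cfg.birth_rate * len(tips)))
        i = rng.integers(len(tips))
        parent = tips.pop(i)
        parent.edge.length = t - birth_times.pop(parent)
        a, b = dendropy.Node(), dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        tips.extend([a, b])
        birth_times[a] = birth_times[b] = t
    t_end = t + rng.exponential(1.0 / (cfg.birth_rate * len(tips)))
    for k, tip in enumerate(tips):
        tip.edge.length = t_end - birth_times[tip]
        tip.taxon = ns.require_taxon(label=f"t{k+1}")
    root.edge.length = 0.0
    return scale_tree_depth(TimeTree(tree), cfg.tree_depth_ma)


def simulate_bm_traits(
    tree: TimeTree,
    sigma2: float,
    group_map: dict[str, str] | pd.Series | None = None,
    effects: dict[str, np.ndarray] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_traits: int = 1,
) -> TraitMatrix:
    """Brownian traits on the tree plus additive group effects and iid noise.

    Each trait column is multivariate normal with covariance ``sigma2 * C``;
    group effect vectors (length ``n_traits``) shift the tips of each group.
    """
    rng = np.random.default_rng(seed)
    C = phylo_vcv(tree).matrix
    labels = tree.tip_labels
    n = len(labels)
    jitter = 1e-12 * max(np.trace(C) / n, 1.0)
    L = np.linalg.cholesky(sigma2 * C + jitter * np.eye(n))
    Y = L @ rng.standard_normal((n, n_traits))
    if noise_sd > 0:
        Y = Y + noise_sd * rng.standard_normal(Y.shape)
    groups = None
    if group_map is not None:
        groups = pd.Series(group_map).reindex(labels)
        eff = effects or {}
        for gname, vec in eff.items():
            mask = (groups == gname).to_numpy()
            Y[mask] += np.asarray(vec, dtype=float)
    data = pd.DataFrame(Y, index=labels,
                        columns=[f"trait_{j+1}" for j in range(n_traits)])
    return TraitMatrix(data=data, groups=groups)


# ---------------------------------------------------------------------------
# Claw geometry


def _arc_landmarks(radius: float, angle_deg: float, rng: np.random.Generator,
                   digit: str) -> ClawLandmarks:
    """Exact three-point sample of an arc with the given central angle."""
    theta = math.radians(angle_deg)
    phase = rng.uniform(0, 2 * math.pi)
    rot = rng.uniform(0, 2 * math.pi)
    shift = rng.uniform(-10, 10, size=2)
    angles = np.array([phase, phase + theta / 2.0, phase + theta])
    pts = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    Rm = np.array([[math.cos(rot), -math.sin(rot)], [math.sin(rot), math.cos(rot)]])
    pts = pts @ Rm.T + shift
    return ClawLandmarks(digit=digit, proximal=tuple(pts[0]),
                         midpoint=tuple(pts[1]), tip=tuple(pts[2]))


def synth_claws(profile: str, seed: int = 0,
                config: dict | None = None) -> dict[str, ClawLandmarks]:
    """Four claws for one pedal-ecology label, as exact three-point arcs."""
    cfg = (config or load_guild_config())["pedal"]
    if profile not in cfg:
        raise ValueError(f"unknown pedal label {profile!r}; choose from {sorted(cfg)}")
    params = cfg[profile]
    rng = np.random.default_rng(seed)
    base_arc = rng.uniform(8.0, 15.0)  # DIII outer arc length (mm)
    claws = {}
    for digit in DIGITS:
        angle = float(np.clip(rng.normal(params["oo_mean"], params["oo_sd"]), 5.0, 355.0))
        ratio = 1.0 if digit == "DIII" else max(
            0.05, rng.normal(params[f"ratio_{digit}"], params["ratio_sd"]))
        arc_len = base_arc * ratio
        radius = arc_len / math.radians(angle)
        claws[digit] = _arc_landmarks(radius, angle, rng, digit)
    return claws


# ---------------------------------------------------------------------------
# Jaw outlines


def synth_jaw(diet_label: str, seed: int = 0, config: dict | None = None,
              n_profile: int = 24) -> dict:
    """Jaw outline + load/constraint points for one diet label.

    Strong-jaw guilds draw deep outlines (high depth/length aspect), weak-jaw
    guilds slender ones.  Returns a dict with ``outline`` (simple polygon,
    CCW), ``attach_point``, ``bite_point``, ``pin_point`` and the drawn
    ``aspect`` — directly consumable by :func:`avidiet.fem.build_jaw_model`.
    """
    cfg = (config or load_guild_config())["jaw"]
    if diet_label in cfg["strong_guilds"]:
        kind = "strong"
    elif diet_label in cfg["weak_guilds"]:
        kind = "weak"
    else:
        raise ValueError(f"unknown diet label {diet_label!r}")
    params = cfg[kind]
    rng = np.random.default_rng(seed)
    L = rng.uniform(*params["length_mm"])
    aspect = max(0.02, rng.normal(params["aspect_mean"], params["aspect_sd"]))
    depth = aspect * L
    tip_frac = 0.15  # residual depth fraction at the rostral tip

    xs = np.linspace(0.0, L, n_profile)
    top = depth * (tip_frac + (1.0 - tip_frac) * (1.0 - xs / L) ** 0.8)
    bottom = np.zeros_like(xs)
    outline = ([(float(x), float(b)) for x, b in zip(xs, bottom)]
               + [(float(x), float(t)) for x, t in zip(xs[::-1], top[::-1])])

    i_attach = max(1, int(round(0.15 * (n_profile - 1))))
    attach_point = (float(xs[i_attach]), float(top[i_attach]))  # vertex on outline
    bite_point = (L, 0.0)
    pin_point = (0.0, 0.0)
    return {
        "outline": outline,
        "attach_point": attach_point,
        "bite_point": bite_point,
        "pin_point": pin_point,
        "aspect": float(aspect),
        "length_mm": float(L),
        "kind": kind,
    }


# ---------------------------------------------------------------------------
# Diet tables


def synth_diet_table(labels, seed: int = 0, include_semi: bool = False) -> pd.DataFrame:
    """Percentage rows constructed to classify back to their generating label.

    Standard rows place the target column just above the standard cut-off;
    semi rows between the semi and standard cut-offs.  The remainder goes to
    a neutral filler column kept below every firing threshold.  Annotation
    columns carry the hardness/husking mode needed for subcategories.
    """
    cutoffs = load_cutoffs()
    rng = np.random.default_rng(seed)
    base_map = {
        "Folivore": ("Folivore", {}),
        "FrugivoreH": ("Frugivore", {"fruit_hardness": "hard"}),
        "FrugivoreS": ("Frugivore", {"fruit_hardness": "soft"}),
        "GranivoreH": ("Granivore", {"granivory_mode": "husk"}),
        "GranivoreS": ("Granivore", {"granivory_mode": "swallow"}),
        "InvertivoreH": ("Invertivore", {"invert_hardness": "hard"}),
        "InvertivoreM": ("Invertivore", {"invert_hardness": "medium"}),
        "InvertivoreS": ("Invertivore", {"invert_hardness": "soft"}),
        "Nectarivore": ("Nectarivore", {}),
        "Piscivore": ("Piscivore", {}),
        "Scavenger": ("Scavenger", {}),
        "TetrapodHunter": ("TetrapodHunter", {}),
    }
    rows = []
    for i, label in enumerate(labels):
        if label not in DIET_CATEGORIES:
            raise ValueError(f"unknown diet label {label!r}")
        pct = {c: 0.0 for c in ("Inv", "Ect", "End", "Vunk", "Fish", "Scav",
                                "Fruit", "Nect", "Seed", "PlantO")}
        annotations: dict = {}
        if label == "Generalist":
            cap = 30.0
            cols = ["Inv", "Fish", "Seed", "Fruit"]
            share = [cap, cap, cap, 100.0 - 3 * cap]
            for c, s in zip(cols, share):
                pct[c] = s
        else:
            base, annotations = base_map[label]
            rule = cutoffs["categories"][base]
            col = rule["column"]
            if include_semi:
                lo, hi = rule["semi"], rule["standard"]
                target = float(lo if hi <= lo else rng.uniform(lo, min(hi, lo + 9.0)))
            else:
                target = float(min(100.0, rule["standard"] + rng.uniform(0.0, 5.0)))
            if base == "TetrapodHunter":
                pct["Ect"] = target / 2.0
                pct["End"] = target - pct["Ect"]
            else:
                pct[col] = target
            filler = 100.0 - target
            # spread filler below every threshold that could fire
            pct["PlantO" if base != "Folivore" else "Fruit"] += min(filler, 40.0)
            leftover = filler - min(filler, 40.0)
            pct["Inv" if base != "Invertivore" else "Nect"] += leftover
        row = {"taxon": f"{label}_{i+1}", "label": label, **{f"Diet-{k}": v
               for k, v in pct.items()}, **annotations}
        rows.append(row)
    return pd.DataFrame(rows).set_index("taxon")


def profile_from_row(row: pd.Series) -> DietProfile:
    """Build a :class:`DietProfile` from a synthetic/EltonTraits-style row."""
    pct = {k.replace("Diet-", ""): float(v) for k, v in row.items()
           if k.startswith("Diet-") and pd.notna(v)}
    return DietProfile(
        percentages=pct,
        fruit_hardness=row.get("fruit_hardness") if pd.notna(row.get("fruit_hardness", np.nan)) else None,
        granivory_mode=row.get("granivory_mode") if pd.notna(row.get("granivory_mode", np.nan)) else None,
        invert_hardness=row.get("invert_hardness") if pd.notna(row.get("invert_hardness", np.nan)) else None,
    )
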