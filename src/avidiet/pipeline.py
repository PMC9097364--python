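"""Synthesis of the four proxies into per-taxon permitted diet sets.

Each proxy yields a :class:`ProxyVerdict` (exclusions and, for classifier
proxies, ranked posteriors).  Consensus is exclusion-union: the permitted set
is the complement of the union of exclusions; the shortlist ranks permitted
categories by mean normalised posterior across classifier proxies.  A proxy
whose top class is excluded by another proxy is logged as a conflict
(exclusion wins, conflict reported, never silently dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .diet import DIET_CATEGORIES, MassEstimate, mass_rule
from .ordination import dapc, lda

__all__ = [
    "ProxyVerdict",
    "ConsensusResult",
    "run_mass_proxy",
    "run_classifier_proxy",
    "synthesize",
]

PROXY_IDS = ("mass", "tm", "ma", "fea")

#: posterior below which a category may be marked excluded by a classifier proxy
DEFAULT_POSTERIOR_FLOOR = 0.05


@dataclass
class ProxyVerdict:
    """One proxy's evidence: per-taxon exclusions and optional posteriors."""

    proxy: str
    excluded: dict[str, set[str]]
    posteriors: pd.DataFrame | None = None  # taxa x categories
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.proxy not in PROXY_IDS:
            raise ValueError(f"proxy must be one of {PROXY_IDS}")
        if self.posteriors is not None:
            for taxon, exc in self.excluded.items():
                if taxon in self.posteriors.index and len(self.posteriors.columns):
                    top = self.posteriors.loc[taxon].idxmax()
                    if top in exc:
                        raise ValueError(
                            f"conflict within proxy {self.proxy}: top-ranked "
                            f"{top!r} is also excluded for {taxon!r}")


@dataclass
class ConsensusResult:
    """Final permitted/excluded sets with shortlist and conflict log."""

    permitted: dict[str, set[str]]
    shortlist: dict[str, list[str]]
    conflicts: list[dict]
    provenance: dict[str, list[dict]]


def run_mass_proxy(masses: dict[str, MassEstimate]) -> ProxyVerdict:
    """Vectorised mass-exclusion rules; identical to per-taxon calls."""
    excluded = {taxon: mass_rule(est) for taxon, est in masses.items()}
    notes = {taxon: f"mass {est.lower:.0f}-{est.upper:.0f} g"
             for taxon, est in masses.items()}
    return ProxyVerdict(proxy="mass", excluded=excluded, notes=notes)


def run_classifier_proxy(
    proxy: str,
    X: pd.DataFrame,
    groups: pd.Series,
    fossils: pd.DataFrame,
    method: str = "lda",
    posterior_floor: float = DEFAULT_POSTERIOR_FLOOR,
    exclude_by_floor: bool = False,
    priors: str = "proportional",
) -> ProxyVerdict:
    """Classify fossil rows against labelled extant rows.

    Exclusions (opt-in via ``exclude_by_floor``) are categories whose fossil
    posterior falls below ``posterior_floor``; the top-ranked class is never
    excluded.  TM verdicts should keep ``exclude_by_floor=False`` (pedal
    ecology maps to diet only as soft evidence).
    """
    if method == "lda":
        res = lda(X, groups, priors=priors, supplementary=fossils)
    elif method == "dapc":
        res = dapc(X, groups, supplementary=fossils, priors=priors)
    else:
        raise ValueError("method must be 'lda' or 'dapc'")
    post = res.supplementary_posteriors
    excluded: dict[str, set[str]] = {}
    for taxon in post.index:
        row = post.loc[taxon]
        top = row.idxmax()
        exc = set()
        if exclude_by_floor:
            exc = {c for c in row.index if row[c] < posterior_floor and c != top}
        excluded[taxon] = exc
    return ProxyVerdict(proxy=proxy, excluded=excluded, posteriors=post)


def synthesize(verdicts: list[ProxyVerdict],
               categories=DIET_CATEGORIES) -> ConsensusResult:
    """Exclusion-union consensus with posterior-mean shortlist ranking."""
    if not verdicts:
        raise ValueError("need at least one proxy verdict")
    taxa: list[str] = []
    for v in verdicts:
        for t in v.excluded:
            if t not in taxa:
                taxa.append(t)
        if v.posteriors is not None:
            for t in v.posteriors.index:
                if t not in taxa:
                    taxa.append(t)

    permitted: dict[str, set[str]] = {}
    shortlist: dict[str, list[str]] = {}
    conflicts: list[dict] = []
    provenance: dict[str, list[dict]] = {t: [] for t in taxa}

    for taxon in taxa:
        union_exc: set[str] = set()
        for v in verdicts:
            exc = v.excluded.get(taxon, set())
            if exc:
                provenance[taxon].append(
                    {"proxy": v.proxy, "rule": "exclusion", "categories": sorted(exc)})
            union_exc |= exc
        perm = set(categories) - union_exc
        permitted[taxon] = perm

        # mean normalised posterior across classifier proxies
        sums: dict[str, float] = {}
        nprox = 0
        for v in verdicts:
            if v.posteriors is None or taxon not in v.posteriors.index:
                continue
            row = v.posteriors.loc[taxon]
            total = row.sum()
            if total <= 0:
                continue
            nprox += 1
            for c, val in (row / total).items():
                sums[c] = sums.get(c, 0.0) + float(val)
            top = row.idxmax()
            if top in union_exc:
                offender = [w.proxy for w in verdicts
                            if top in w.excluded.get(taxon, set())]
                conflicts.append({"taxon": taxon, "proxy": v.proxy,
                                  "top_class": top, "excluded_by": offender})
        if nprox:
            ranked = sorted((c for c in perm),
                            key=lambda c: (-sums.get(c, 0.0) / nprox, c))
        else:
            ranked = sorted(perm)
        shortlist[taxon] = ranked
    return ConsensusResult(permitted=permitted, shortlist=shortlist,
                           conflicts=conflicts, provenance=provenance)
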