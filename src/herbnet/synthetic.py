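"""Synthetic catalogs with controlled statistical structure.

The generator emulates the statistical shape of the data sources the
analysis assumes, without any chemistry: a TCMID-like herb→compound
catalog (8159 herbs drawing from a shared pool of 43,413 compounds, so
popular compounds are shared by many herbs), BATMAN-like compound→target
prediction scores on a 0–100 scale with a configurable probability mass
above the 55 cutoff, and a KEGG-scale target–pathway bipartite map
(325 pathways, 7373 proteins, 29,039 memberships).  A scaled-down "desk"
preset keeps the same shape at a size where a full null-model run takes
seconds.  Generation is a pure function of the parameters, including the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from herbnet.catalog import (Catalog, CompoundRecord, HerbRecord,
                             PathwayMembership, TargetInteraction, TargetRecord)
from herbnet.errors import ParameterError
from herbnet.screening import ScreeningConfig, adme_filter

__all__ = ["GeneratorParams", "default_params", "desk_params",
           "generate_catalog", "plant_enrichment"]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic catalog generator.

    ``bin_probs`` are the herb proportions over the four compound-count
    bins (≤10 / 11–20 / 21–40 / ≥41); within a bin, counts are uniform
    (the last bin spans 41..``bin4_max``).  ``ob_pass_prob`` and
    ``dl_pass_prob`` are the marginal probabilities of clearing OB ≥ 30
    and DL ≥ 0.18; values are drawn uniformly on the pass or fail side of
    the threshold.  ``score_above_prob`` is the probability mass of a
    prediction score above 55 (scores live on a 0–100 scale);
    ``mean_interactions`` is the Poisson mean of targets per compound.
    ``popularity_exponent`` shapes the compound-sharing law: herbs draw
    from the pool with weight ∝ rank^(-exponent), so a few compounds are
    shared by many herbs.
    """

    n_herbs: int = 8159
    n_compounds_pool: int = 43_413
    n_targets: int = 7373
    n_pathways: int = 325
    n_memberships: int = 29_039
    bin_probs: tuple[float, float, float, float] = (0.40, 0.30, 0.20, 0.10)
    bin4_max: int = 60
    ob_pass_prob: float = 0.5
    dl_pass_prob: float = 0.5
    mean_interactions: float = 3.0
    score_above_prob: float = 0.35
    popularity_exponent: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_herbs", "n_compounds_pool", "n_targets",
                     "n_pathways", "n_memberships"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("ob_pass_prob", "dl_pass_prob", "score_above_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0,1], got {v}")
        if abs(sum(self.bin_probs) - 1.0) > 1e-9 or min(self.bin_probs) < 0:
            raise ParameterError("bin_probs must be non-negative and sum to 1")
        if self.n_memberships > self.n_targets * self.n_pathways:
            raise ParameterError("n_memberships exceeds n_targets * n_pathways")
        if self.bin4_max < 41:
            raise ParameterError("bin4_max must be >= 41")
        if self.n_compounds_pool < self.bin4_max:
            raise ParameterError("compound pool smaller than the largest herb")


def default_params(seed: int = 0) -> GeneratorParams:
    """Full-database-scale defaults (8159 herbs, 325 pathways, ...)."""
    return GeneratorParams(seed=seed)


def desk_params(seed: int = 0) -> GeneratorParams:
    """Scaled-down preset for fast experimentation and testing.

    300 herbs over an 800-compound pool, 400 targets, 40 pathways and
    194 memberships.  The membership count scales with the product of
    the two axis reductions, preserving the full map's bipartite density
    — each pathway covers ~1.2% of the proteins, and any two pathways
    overlap in ~1.2% of their members, exactly as at full scale — which
    is what keeps cross-pathway dependence of null centralities
    realistic.  (The per-protein membership count is necessarily smaller;
    both cannot be preserved at once in a scaled bipartite map.)
    """
    return GeneratorParams(n_herbs=300, n_compounds_pool=800, n_targets=400,
                           n_pathways=40, n_memberships=194, seed=seed)


_BIN_RANGES = ((1, 10), (11, 20), (21, 40), (41, None))


def generate_catalog(params: GeneratorParams) -> Catalog:
    """Draw a catalog from the configured laws; reproducible from seed."""
    rng = np.random.default_rng(params.seed)
    cat = Catalog()

    width = len(str(params.n_compounds_pool))
    pool = [f"c{str(i + 1).zfill(width)}" for i in range(params.n_compounds_pool)]
    for cid in pool:
        ob = (rng.uniform(30.0, 100.0) if rng.random() < params.ob_pass_prob
              else rng.uniform(0.0, 30.0))
        dl = (rng.uniform(0.18, 1.0) if rng.random() < params.dl_pass_prob
              else rng.uniform(0.0, 0.18))
        cat.compounds[cid] = CompoundRecord(compound_id=cid, name=cid,
                                            ob=float(ob), dl=float(dl))

    # popularity-weighted sampling without replacement via the Gumbel trick
    log_pop = -params.popularity_exponent * np.log(
        np.arange(1, params.n_compounds_pool + 1, dtype=float))
    hwidth = len(str(params.n_herbs))
    bin_edges = list(_BIN_RANGES)
    bin_edges[-1] = (41, params.bin4_max)
    for i in range(params.n_herbs):
        b = int(rng.choice(4, p=params.bin_probs))
        lo, hi = bin_edges[b]
        count = int(rng.integers(lo, hi + 1))
        keys = log_pop + rng.gumbel(size=params.n_compounds_pool)
        idx = np.argpartition(keys, -count)[-count:]
        hid = f"h{str(i + 1).zfill(hwidth)}"
        cat.herbs[hid] = HerbRecord(
            herb_id=hid, latin_name=f"Herba synthetica {i + 1}",
            pinyin_name=hid.upper(),
            compound_ids=frozenset(pool[j] for j in idx))

    tids = [str(10_000 + i) for i in range(params.n_targets)]
    for i, tid in enumerate(tids):
        cat.targets[tid] = TargetRecord(
            target_id=tid, description=f"synthetic protein {i + 1}")
    for cid in pool:
        k = min(int(rng.poisson(params.mean_interactions)), params.n_targets)
        if k == 0:
            continue
        for j in rng.choice(params.n_targets, size=k, replace=False):
            score = (rng.uniform(55.0, 100.0)
                     if rng.random() < params.score_above_prob
                     else rng.uniform(1.0, 55.0))
            tid = tids[int(j)]
            cat.interactions[(cid, tid)] = TargetInteraction(
                compound_id=cid, target_id=tid, score=float(score))

    pwidth = len(str(params.n_pathways))
    pnames = [f"pathway_{str(i + 1).zfill(pwidth)}"
              for i in range(params.n_pathways)]
    flat = rng.choice(params.n_pathways * params.n_targets,
                      size=params.n_memberships, replace=False)
    for f in flat:
        p, t = divmod(int(f), params.n_targets)
        cat.memberships.add(PathwayMembership(pnames[p], tids[t]))
    return cat


def plant_enrichment(catalog: Catalog, pathway_name: str, boost: float,
                     seed: int, herb_ids: set[str] | None = None,
                     screening: ScreeningConfig = ScreeningConfig()) -> Catalog:
    """Boost the screened compound-degree of one pathway's member targets.

    The screened degree of a target is the number of distinct
    ADME-passing compounds of ``herb_ids`` (all herbs when omitted)
    linked to it with a score above the cutoff.  Planting adds
    round((boost-1) * d_mean * n_members) new interactions with scores in
    (80, 100), spread evenly (round-robin) over the member targets, where
    d_mean is the members' mean screened degree — so the members' mean
    degree is multiplied by ``boost`` up to rounding.  New edges go to
    eligible compounds not yet linked to the receiving target, least
    herb-shared compounds first: the planted signal is thereby specific
    to ``herb_ids`` rather than riding on pool-wide popular compounds,
    which random herb selections would pick up too (signal planted into
    the null cancels itself and probes nothing).  All other records are
    untouched; reproducible from ``seed``.  Raises ``KeyError`` for an
    unknown pathway and ``ValueError`` for boost < 1.
    """
    if boost < 1:
        raise ValueError(f"boost must be >= 1, got {boost}")
    members = sorted({m.target_id for m in catalog.memberships
                      if m.pathway_name == pathway_name})
    if not members:
        raise KeyError(f"unknown pathway {pathway_name!r}")
    if herb_ids is None:
        herb_ids = set(catalog.herbs)
    passing = adme_filter(catalog, screening)
    herb_freq: dict[str, int] = {}
    for rec in catalog.herbs.values():
        for c in rec.compound_ids:
            herb_freq[c] = herb_freq.get(c, 0) + 1
    eligible = sorted(
        set().union(*(catalog.herbs[h].compound_ids for h in herb_ids)) & passing,
        key=lambda c: (herb_freq[c], c))

    out = Catalog(herbs=dict(catalog.herbs), compounds=dict(catalog.compounds),
                  interactions=dict(catalog.interactions),
                  targets=dict(catalog.targets),
                  memberships=set(catalog.memberships))
    degree = {tid: sum(
        1 for c in eligible
        if (c, tid) in catalog.interactions
        and (catalog.interactions[(c, tid)].score or 0) > screening.score_min)
        for tid in members}
    total_new = round((boost - 1) * sum(degree.values()))
    rng = np.random.default_rng(seed)
    added = 0
    while added < total_new:
        progressed = False
        for tid in members:  # round-robin keeps per-target degrees even
            if added >= total_new:
                break
            cid = next((c for c in eligible
                        if (c, tid) not in out.interactions), None)
            if cid is None:
                continue
            out.interactions[(cid, tid)] = TargetInteraction(
                compound_id=cid, target_id=tid,
                score=float(rng.uniform(80.0, 100.0)))
            added += 1
            progressed = True
        if not progressed:  # every member target saturated
            break
    return out
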