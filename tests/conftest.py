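"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

import herbnet
from herbnet.catalog import (Catalog, CompoundRecord, HerbRecord,
                             PathwayMembership, TargetInteraction, TargetRecord)
from herbnet.network import TripartiteNetwork

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

# study conditions shared by the statistical tests: desk-scale catalog and
# a 20-herb observed profile matching the generator's bin proportions
DESK_SEED = 11
OBSERVED_PROFILE = (8, 6, 4, 2)


@pytest.fixture(scope="session")
def fixture_catalog() -> Catalog:
    return herbnet.load_fixture()


@pytest.fixture(scope="session")
def desk_catalog() -> Catalog:
    return herbnet.generate_catalog(herbnet.desk_params(seed=DESK_SEED))


def make_catalog(herbs: dict[str, set[str]],
                 compounds: dict[str, tuple[float | None, float | None]],
                 interactions: dict[tuple[str, str], float | None],
                 memberships: set[tuple[str, str]] = frozenset()) -> Catalog:
    """Hand-build a small catalog from plain literals."""
    cat = Catalog()
    for cid, (ob, dl) in compounds.items():
        cat.compounds[cid] = CompoundRecord(
            compound_id=cid, name=cid, ob=ob, dl=dl,
            prescreened=(ob is None and dl is None))
    for hid, cids in herbs.items():
        cat.herbs[hid] = HerbRecord(herb_id=hid, compound_ids=frozenset(cids))
    tids = {t for _, t in interactions} | {t for _, t in memberships}
    for tid in sorted(tids):
        cat.targets[tid] = TargetRecord(target_id=tid)
    for (cid, tid), score in interactions.items():
        cat.interactions[(cid, tid)] = TargetInteraction(cid, tid, score)
    for p, t in memberships:
        cat.memberships.add(PathwayMembership(p, t))
    return cat


def random_small_network(rng: np.random.Generator) -> TripartiteNetwork:
    """A random scored network: ≤8 pathways, ≤10 genes, ≤15 compounds."""
    n_p = int(rng.integers(1, 9))
    n_t = int(rng.integers(1, 11))
    n_c = int(rng.integers(1, 16))
    pathways = [f"P{i}" for i in range(n_p)]
    targets = [f"T{j}" for j in range(n_t)]
    compounds = [f"C{k}" for k in range(n_c)]
    ct, scores = set(), {}
    for k in compounds:
        for j in targets:
            if rng.random() < 0.3:
                ct.add((k, j))
                scores[(k, j)] = float(rng.uniform(1.0, 100.0))
    hit_targets = frozenset(j for _, j in ct)
    pt = {(i, j) for i in pathways for j in hit_targets if rng.random() < 0.5}
    return TripartiteNetwork(
        herb_set=frozenset({"H"}),
        compound_set=frozenset(compounds),
        target_set=hit_targets,
        pathway_set=frozenset(i for i, _ in pt),
        herb_compound_edges=frozenset(("H", c) for c in compounds),
        compound_target_edges=frozenset(ct),
        pathway_target_edges=frozenset(pt),
        scores=scores)


def oracle_centralities(net: TripartiteNetwork) -> dict[str, float]:
    """Brute-force triple loop applying the indicator definitions literally.

    Independent of the production code: iterates every (pathway i,
    target j, compound k) combination, testing edge indicators one by
    one; single-compound genes use denominator 1.
    """
    out: dict[str, float] = {}
    for i in sorted(net.pathway_set):
        s_i = 0.0
        for j in sorted(net.target_set):
            if (i, j) not in net.pathway_target_edges:
                continue
            num, c = 0.0, 0
            for k in sorted(net.compound_set):
                if (k, j) in net.compound_target_edges:
                    num += math.sqrt(net.scores[(k, j)])
                    c += 1
            if c == 0:
                w = 0.0
            elif c == 1:
                w = num
            else:
                w = num / math.log(c)
            s_i += w
        out[i] = s_i
    return out


def bh_oracle(ps: np.ndarray) -> np.ndarray:
    """Independent Benjamini–Hochberg step-up: q_(i) = min_{j>=i} m p_(j)/j."""
    m = len(ps)
    order = np.argsort(ps, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * ps[idx] / rank)
        q[idx] = running
    return q
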