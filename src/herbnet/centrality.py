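"""Weighted degree centrality of pathways in a tripartite network.

Each target gene *j* receives a weight

    w_j = ( sum_k sqrt(p_jk) * e_jk ) / ln( sum_k e_jk )

where *p_jk* is the prediction score of the compound-*k*–target-*j*
interaction and *e_jk* the binary edge indicator; the centrality of a
pathway *i* is the sum of w_j over its connected targets:

    S_i = sum_j w_j * e_ij .

The denominator ln(c) vanishes for a gene hit by exactly one compound
(c = 1).  Two policies are offered: ``singleton_one`` (default) replaces
the denominator by 1 for c = 1, keeping the weight finite and the null
model internally consistent; ``strict`` raises
:class:`UndefinedWeightError` instead.  A gene with no compound edges has
weight 0 under either policy (empty sum).
"""

from __future__ import annotations

import math

import pandas as pd

from herbnet.errors import DataError, UndefinedWeightError
from herbnet.network import TripartiteNetwork

__all__ = ["STRICT", "SINGLETON_ONE", "gene_weight", "gene_weights",
           "pathway_centralities", "centrality_frame"]

STRICT = "strict"
SINGLETON_ONE = "singleton_one"
_MODES = (STRICT, SINGLETON_ONE)


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")


def gene_weight(net: TripartiteNetwork, target_id: str,
                mode: str = SINGLETON_ONE) -> float:
    """Weight of one target gene: sum of root scores over ln(compound count).

    Raises :class:`DataError` if any of the gene's edges lacks a score and
    :class:`UndefinedWeightError` for a single-compound gene under
    ``strict``.
    """
    _check_mode(mode)
    compounds = net.compounds_of_target(target_id)
    c = len(compounds)
    if c == 0:
        return 0.0
    numerator = 0.0
    for cid in compounds:
        score = net.scores.get((cid, target_id))
        if score is None:
            raise DataError(
                f"edge ({cid!r}, {target_id!r}) carries no prediction score; "
                "centrality needs scored interactions")
        numerator += math.sqrt(score)
    if c == 1:
        if mode == STRICT:
            raise UndefinedWeightError(
                f"gene {target_id!r} has exactly one compound edge: "
                "denominator ln(1) = 0 (use mode 'singleton_one')")
        return numerator  # denominator 1
    return numerator / math.log(c)


def gene_weights(net: TripartiteNetwork,
                 mode: str = SINGLETON_ONE) -> dict[str, float]:
    """Weights for every target in the network."""
    return {t: gene_weight(net, t, mode=mode) for t in net.target_set}


def pathway_centralities(net: TripartiteNetwork,
                         mode: str = SINGLETON_ONE) -> dict[str, float]:
    """Weighted degree centrality S_i for every pathway in the network.

    S_i sums the weights of the pathway's connected targets; a pathway
    with no target edges scores 0.  Propagates gene-weight errors.
    """
    _check_mode(mode)
    weights = gene_weights(net, mode=mode)
    out: dict[str, float] = {p: 0.0 for p in net.pathway_set}
    for p, t in net.pathway_target_edges:
        out[p] += weights[t]
    return out


def centrality_frame(net: TripartiteNetwork,
                     mode: str = SINGLETON_ONE) -> pd.DataFrame:
    """Tabular view: pathway_name, S, n_targets, sorted by S desc then name."""
    cent = pathway_centralities(net, mode=mode)
    n_targets: dict[str, int] = {p: 0 for p in net.pathway_set}
    for p, _ in net.pathway_target_edges:
        n_targets[p] += 1
    rows = sorted(cent.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame([{"pathway_name": p, "S": s, "n_targets": n_targets[p]}
                         for p, s in rows])
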