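"""ADME screening of compounds and score screening of interactions.

Compounds pass when oral bioavailability OB ≥ ``ob_min`` (percent scale,
default 30) and drug-likeness DL ≥ ``dl_min`` (default 0.18), both
boundaries inclusive.  Compound–target interactions pass when their
prediction score is strictly greater than ``score_min`` (default 55).
Prescreened compounds (no OB/DL on record) bypass the ADME stage; the
score scale is database-dependent, so the 55 cutoff is meaningful only
for scores generated or recorded on a 0–100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from herbnet.catalog import Catalog, TargetInteraction
from herbnet.errors import DataError

__all__ = ["ScreeningConfig", "adme_filter", "interaction_filter",
           "screening_summary"]


@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds for the two screening stages.

    ``ob_min`` and ``dl_min`` are inclusive; ``score_min`` is exclusive.
    ``skip_prescreened`` lets prescreened compounds (and score-absent
    interactions of prescreened compounds) pass unconditionally.
    """

    ob_min: float = 30.0
    dl_min: float = 0.18
    score_min: float = 55.0
    skip_prescreened: bool = True

    def __post_init__(self) -> None:
        if self.ob_min < 0:
            raise ValueError(f"ob_min must be >= 0, got {self.ob_min}")
        if not (0.0 <= self.dl_min <= 1.0):
            raise ValueError(f"dl_min must be in [0,1], got {self.dl_min}")
        if self.score_min <= 0:
            raise ValueError(f"score_min must be > 0, got {self.score_min}")


def adme_filter(catalog: Catalog,
                config: ScreeningConfig = ScreeningConfig()) -> set[str]:
    """Return the compound ids passing OB/DL screening.

    Prescreened compounds pass unconditionally when
    ``config.skip_prescreened`` is set; a non-prescreened compound with a
    missing OB or DL raises :class:`DataError` naming the compound.
    """
    kept: set[str] = set()
    for cid, comp in catalog.compounds.items():
        if comp.prescreened and config.skip_prescreened:
            kept.add(cid)
            continue
        if comp.ob is None or comp.dl is None:
            raise DataError(f"compound {cid!r} lacks OB/DL and is not prescreened")
        if comp.ob >= config.ob_min and comp.dl >= config.dl_min:
            kept.add(cid)
    return kept


def interaction_filter(catalog: Catalog, passing_compounds: set[str],
                       config: ScreeningConfig = ScreeningConfig()
                       ) -> set[TargetInteraction]:
    """Return interactions of passing compounds with score > ``score_min``.

    Score-absent interactions of prescreened compounds pass when
    ``config.skip_prescreened`` is set (they were screened upstream);
    a score-absent interaction of a screenable compound raises
    :class:`DataError`.
    """
    kept: set[TargetInteraction] = set()
    for inter in catalog.interactions.values():
        if inter.compound_id not in passing_compounds:
            continue
        if inter.score is None:
            comp = catalog.compounds.get(inter.compound_id)
            if config.skip_prescreened and comp is not None and comp.prescreened:
                kept.add(inter)
                continue
            raise DataError(
                f"interaction ({inter.compound_id!r}, {inter.target_id!r}) "
                "has no prediction score")
        if inter.score > config.score_min:
            kept.add(inter)
    return kept


def screening_summary(before: Catalog, compounds_kept: set[str],
                      interactions_kept: set[TargetInteraction]) -> pd.DataFrame:
    """Per-herb and overall counts before/after both screening stages.

    One row per herb plus a TOTAL row with distinct-record overall counts.
    """
    kept_by_compound: dict[str, int] = {}
    for inter in interactions_kept:
        kept_by_compound[inter.compound_id] = kept_by_compound.get(inter.compound_id, 0) + 1
    all_by_compound: dict[str, int] = {}
    for inter in before.interactions.values():
        all_by_compound[inter.compound_id] = all_by_compound.get(inter.compound_id, 0) + 1

    rows = []
    for hid in sorted(before.herbs):
        cids = before.herbs[hid].compound_ids
        kept_cids = cids & compounds_kept
        rows.append({
            "herb_id": hid,
            "compounds_before": len(cids),
            "compounds_after": len(kept_cids),
            "interactions_before": sum(all_by_compound.get(c, 0) for c in cids),
            "interactions_after": sum(kept_by_compound.get(c, 0) for c in kept_cids),
        })
    rows.append({
        "herb_id": "TOTAL",
        "compounds_before": len(before.compounds),
        "compounds_after": len(compounds_kept),
        "interactions_before": len(before.interactions),
        "interactions_after": len(interactions_kept),
    })
    return pd.DataFrame(rows)
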