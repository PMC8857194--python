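"""End-to-end pipeline orchestration and report writing.

Stage order: select herbs → ADME screening → score screening → tripartite
network → counting tables → weighted degree centrality → null model →
significance.  On a score-absent catalog (such as the packaged fixture)
the centrality and null stages are skipped with a logged notice; the
counting tables are always produced.  A :class:`RunConfig` plus its seed
fully determines every output byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import herbnet
from herbnet.catalog import Catalog, load_catalog, load_fixture
from herbnet.centrality import centrality_frame, pathway_centralities
from herbnet.network import (TripartiteNetwork, build_network,
                             compound_count_per_target, export_network,
                             network_summary, pathway_frequency_table)
from herbnet.nullmodel import (NullConfig, bin_profile, null_ensemble,
                               significance_table)
from herbnet.screening import (ScreeningConfig, adme_filter,
                               interaction_filter, screening_summary)
from herbnet.synthetic import GeneratorParams, generate_catalog

log = logging.getLogger("herbnet")

__all__ = ["RunConfig", "ResultsBundle", "run_pipeline", "write_reports"]


@dataclass(frozen=True)
class RunConfig:
    """One fully specified pipeline run.

    Exactly one catalog source must be set: ``fixture=True``,
    ``catalog_path`` (+ ``catalog_format``), or ``generator``.  ``herbs``
    selects the observed herb set (None = every catalog herb);
    ``n_random_herbs`` instead draws that many herbs uniformly using
    ``seed``.  ``null`` enables the null-model stage.
    """

    fixture: bool = False
    catalog_path: str | None = None
    catalog_format: str = "tabular"
    generator: GeneratorParams | None = None
    herbs: tuple[str, ...] | None = None
    n_random_herbs: int | None = None
    screening: ScreeningConfig = ScreeningConfig()
    null: NullConfig | None = None
    seed: int = 0
    export_formats: tuple[str, ...] = ("tsv",)

    def __post_init__(self) -> None:
        sources = sum([self.fixture, self.catalog_path is not None,
                       self.generator is not None])
        if sources != 1:
            raise ValueError("exactly one catalog source must be configured")


@dataclass
class ResultsBundle:
    """Everything one run produces, reproducible from config + seed."""

    catalog: Catalog
    network: TripartiteNetwork
    screening_summary: pd.DataFrame
    network_summary: dict[str, int]
    target_table: pd.DataFrame
    pathway_table: pd.DataFrame
    centrality_table: pd.DataFrame | None
    significance: pd.DataFrame | None
    metadata: dict


def _load(config: RunConfig) -> Catalog:
    if config.fixture:
        return load_fixture()
    if config.catalog_path is not None:
        return load_catalog(config.catalog_path, format=config.catalog_format)
    assert config.generator is not None
    return generate_catalog(config.generator)


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute all stages; see the module docstring for the stage order."""
    catalog = _load(config)
    if config.n_random_herbs is not None:
        rng = np.random.default_rng(config.seed)
        all_ids = sorted(catalog.herbs)
        idx = rng.choice(len(all_ids), size=config.n_random_herbs, replace=False)
        herb_ids = {all_ids[i] for i in idx}
    elif config.herbs is not None:
        herb_ids = set(config.herbs)
    else:
        herb_ids = set(catalog.herbs)
    log.info("selected %d herbs", len(herb_ids))

    compounds_kept = adme_filter(catalog, config.screening)
    interactions_kept = interaction_filter(catalog, compounds_kept,
                                           config.screening)
    screen_df = screening_summary(catalog, compounds_kept, interactions_kept)
    net = build_network(herb_ids, catalog, interactions_kept,
                        compounds_kept=compounds_kept)
    summary = network_summary(net)
    log.info("network: %s", summary)

    scored = all(net.scores.get(e) is not None for e in net.compound_target_edges)
    centrality_df = None
    significance = None
    mode = config.null.mode if config.null is not None else "singleton_one"
    if scored and net.compound_target_edges:
        centrality_df = centrality_frame(net, mode=mode)
        if config.null is not None:
            ensemble = null_ensemble(catalog, net, config.null, config.screening)
            observed = pathway_centralities(net, mode=mode)
            significance = significance_table(observed, ensemble,
                                              alpha=config.null.alpha)
    elif config.null is not None or not scored:
        log.info("catalog is score-absent: centrality and null stages skipped")

    metadata = {
        "herbnet_version": herbnet.__version__,
        "seed": config.seed,
        "n_herbs_selected": len(herb_ids),
        "screening": {"ob_min": config.screening.ob_min,
                      "dl_min": config.screening.dl_min,
                      "score_min": config.screening.score_min,
                      "skip_prescreened": config.screening.skip_prescreened},
        "bin_profile": list(bin_profile(catalog, herb_ids)),
        "network": summary,
        "scored": bool(scored),
    }
    if config.null is not None:
        metadata["null"] = {"replicates": config.null.replicates,
                            "seed": config.null.seed,
                            "alpha": config.null.alpha,
                            "mode": config.null.mode,
                            "exclude_observed": config.null.exclude_observed,
                            "executed": significance is not None}
    return ResultsBundle(
        catalog=catalog, network=net, screening_summary=screen_df,
        network_summary=summary,
        target_table=compound_count_per_target(net),
        pathway_table=pathway_frequency_table(net),
        centrality_table=centrality_df, significance=significance,
        metadata=metadata)


def write_reports(bundle: ResultsBundle, outdir: str | Path,
                  export_formats: tuple[str, ...] = ("tsv",)) -> list[Path]:
    """Write the bundle's tables, network exports and run metadata.

    Stable filenames; re-running overwrites with identical bytes.
    Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def tsv(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", index=False, lineterminator="\n")
        written.append(p)

    tsv(bundle.screening_summary, "screening_summary.tsv")
    tsv(bundle.target_table, "target_compound_counts.tsv")
    tsv(bundle.pathway_table, "pathway_frequencies.tsv")
    if bundle.centrality_table is not None:
        tsv(bundle.centrality_table, "centrality.tsv")
    if bundle.significance is not None:
        tsv(bundle.significance, "significance.tsv")
    for fmt in export_formats:
        if fmt == "tsv":
            written += export_network(bundle.network, outdir / "network", "tsv")
        elif fmt == "graphml":
            written += export_network(bundle.network, outdir / "network.graphml",
                                      "graphml")
        else:
            raise ValueError(f"unsupported export format {fmt!r}")
    meta = outdir / "run_metadata.yaml"
    with open(meta, "w", encoding="utf-8") as fh:
        yaml.safe_dump(bundle.metadata, fh, sort_keys=True)
    written.append(meta)
    return written
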