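"""End-to-end study workflow: simulate/load -> networks -> DC + DE ->
enrichment -> core-set validation.

One root seed deterministically spawns a seed per stage, so a run is fully
reproducible and individual stages can be re-run from the written
intermediates. Every artifact starts with comment lines echoing the package
version, the configuration hash and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .connectivity import (
    RandomGraphSpec,
    compare_degree_distributions,
    dc_permutation_test,
    degrees,
    er_random_graph,
    interplay_correlations,
)
from .enrichment import (
    core_set_comparison,
    dec_enrichment,
    dec_statistic,
    rs_de_enrichment,
)
from .expression import ttest_de
from .io import (
    ExpressionDataset,
    GeneSetCollection,
    gene_table_frame,
    read_expression,
    read_gmt,
    write_expression,
    write_gene_table,
    write_gmt,
    write_pathway_table,
    write_report,
)
from .network import DEFAULT_ALPHA, DEFAULT_FDR_Q, infer_network
from .simulate import SyntheticConfig, SyntheticTruth, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "auto_gene_sets"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full analysis run.

    Either ``expression_path``/``phenotype_path`` point at real data, or
    ``synthetic`` describes a generated study (the default). Thresholds
    mirror the network-inference defaults (``alpha`` 0.05, FDR ceiling
    0.20); ``b_permutations`` drives both the DC test and the DE-enrichment
    label permutations, ``enrichment_draws`` the DEC gene-set resampling,
    and ``coreset_draws`` the core-set validation.
    """

    outdir: str = "dcnet_run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    expression_path: str | None = None
    phenotype_path: str | None = None
    gmt_path: str | None = None
    core_gmt_path: str | None = None
    alpha: float = DEFAULT_ALPHA
    fdr_q: float = DEFAULT_FDR_Q
    b_permutations: int = 1000
    enrichment_draws: int = 1000
    coreset_draws: int = 10000
    n_random_sets: int = 10
    random_set_size: int = 20
    min_group_size: int = 11

    def __post_init__(self) -> None:
        for name in ("alpha", "fdr_q"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")

    def config_hash(self) -> str:
        # outdir is excluded: the hash identifies the analysis, not where
        # its results land
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def auto_gene_sets(
    dataset: ExpressionDataset,
    truth: SyntheticTruth | None,
    n_random: int,
    set_size: int,
    rng: np.random.Generator,
) -> tuple[GeneSetCollection, list[str]]:
    """Build a pathway collection for a synthetic study.

    The planted DC and DE gene sets become named pathways (the "core set"
    an analyst would hope to recover) alongside random decoy sets drawn from
    the gene universe.
    """
    genes = dataset.gene_ids
    sets: dict[str, list[str]] = {}
    core: list[str] = []
    if truth is not None and truth.planted_dc_genes:
        sets["PLANTED_DC"] = sorted(truth.planted_dc_genes)
        core.append("PLANTED_DC")
    if truth is not None and truth.planted_de_genes:
        sets["PLANTED_DE"] = sorted(truth.planted_de_genes)
        core.append("PLANTED_DE")
    size = min(set_size, len(genes))
    for i in range(n_random):
        idx = rng.choice(len(genes), size=size, replace=False)
        sets[f"RANDOM_{i + 1:02d}"] = sorted(genes[j] for j in idx)
    descriptions = {name: "synthetic pathway" for name in sets}
    return GeneSetCollection(sets, descriptions), core


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def _done(name: str, t0: float) -> None:
    logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run the whole workflow and write the five result artifacts.

    Returns the paths of: the per-gene table, the per-pathway table, the
    degree-distribution report, the DC/DE interplay report and the core-set
    comparison report. Fully deterministic given (config, seed).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [
        f"dcnet {__version__}",
        f"config_hash={config.config_hash()}",
        f"seed={config.seed}",
    ]
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("simulate", "dc", "rs_de", "dec", "coreset", "er", "sets"),
            ss.spawn(7),
        )
    }

    # -- data ------------------------------------------------------------
    t0 = _stage("data")
    truth: SyntheticTruth | None = None
    if config.expression_path and config.phenotype_path:
        dataset = read_expression(config.expression_path, config.phenotype_path)
    else:
        syn = dataclasses.replace(config.synthetic, seed=seeds["simulate"])
        dataset, truth = generate_dataset(syn)
        write_expression(dataset, outdir / "expression.tsv", outdir / "phenotype.tsv")
        write_report(
            [
                {"gene": g, "planted": role}
                for role, members in (
                    ("dc", sorted(truth.planted_dc_genes)),
                    ("de", sorted(truth.planted_de_genes)),
                )
                for g in members
            ],
            outdir / "truth.tsv",
            header,
        )
    _done("data", t0)

    ref, cond = dataset.levels

    # -- networks + DC ---------------------------------------------------
    t0 = _stage("networks/dc")
    try:
        net_ref = infer_network(dataset, ref, config.alpha, config.fdr_q, config.min_group_size)
        net_cond = infer_network(dataset, cond, config.alpha, config.fdr_q, config.min_group_size)
        dc = dc_permutation_test(
            dataset,
            n_perm=config.b_permutations,
            seed=seeds["dc"],
            alpha=config.alpha,
            q=config.fdr_q,
            min_group_size=config.min_group_size,
        )
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise RuntimeError(f"stage networks/dc failed: {exc}") from exc
    _done("networks/dc", t0)

    # -- DE --------------------------------------------------------------
    t0 = _stage("de")
    try:
        de = ttest_de(dataset)
    except Exception as exc:
        raise RuntimeError(f"stage de failed: {exc}") from exc
    _done("de", t0)

    gene_table = gene_table_frame(
        dc.gene_ids, de.p_de, de.fdr_de, de.t, dc.p_dc, dc.fdr_dc,
        dc.lost, dc.gained, dc.delta_k,
    )
    gene_table_path = outdir / "gene_table.tsv"
    write_gene_table(gene_table, gene_table_path, header)

    # -- degree distributions vs paired phenotype and ER null ------------
    t0 = _stage("degrees")
    k_ref = degrees(net_ref)
    k_cond = degrees(net_cond)
    rows = []
    loss = compare_degree_distributions(k_ref, k_cond, "greater")
    rows.append(
        {"comparison": f"{ref}_vs_{cond}", "tail": loss.tail, "D": loss.statistic, "p": loss.p}
    )
    for label, k in ((ref, k_ref), (cond, k_cond)):
        er = er_random_graph(
            RandomGraphSpec(len(k), float(np.mean(k)), seed=seeds["er"])
        )
        ks = compare_degree_distributions(k, degrees(er), "two-sided")
        rows.append(
            {"comparison": f"{label}_vs_ER", "tail": ks.tail, "D": ks.statistic, "p": ks.p}
        )
    for label, k, net in ((ref, k_ref, net_ref), (cond, k_cond, net_cond)):
        rows.append(
            {
                "comparison": f"{label}_summary",
                "tail": "",
                "D": "",
                "p": "",
                "mean_degree": float(np.mean(k)),
                "n_edges": net.n_edges,
            }
        )
    degree_report_path = outdir / "degree_report.tsv"
    write_report(rows, degree_report_path, header)
    _done("degrees", t0)

    # -- interplay -------------------------------------------------------
    t0 = _stage("interplay")
    interplay = interplay_correlations(dc, de)
    interplay_rows = [
        {
            "name": e.name,
            "rho": e.rho if e.rho is not None else "NA",
            "p": e.p if e.p is not None else "NA",
            "tail": e.tail or "NA",
            "note": e.note,
        }
        for e in interplay["correlations"]
    ]
    interplay_path = outdir / "interplay_report.tsv"
    write_report(interplay_rows, interplay_path, header)
    _done("interplay", t0)

    # -- enrichment ------------------------------------------------------
    t0 = _stage("enrichment")
    if config.gmt_path:
        sets = read_gmt(config.gmt_path)
        core = list(read_gmt(config.core_gmt_path)) if config.core_gmt_path else []
    else:
        sets, core = auto_gene_sets(
            dataset,
            truth,
            config.n_random_sets,
            config.random_set_size,
            np.random.default_rng(seeds["sets"]),
        )
        write_gmt(sets, outdir / "gene_sets.gmt")

    de_enr = rs_de_enrichment(
        dataset, sets, n_perm=config.b_permutations, seed=seeds["rs_de"]
    )
    floor = 1.0 / config.b_permutations
    u = dec_statistic(de.p_de, dc.p_dc, floor)
    dec_enr = dec_enrichment(
        u, dataset.gene_ids, sets, n_draws=config.enrichment_draws, seed=seeds["dec"]
    )

    shared = [n for n in de_enr.names if n in set(dec_enr.names)]
    pathway_table = _pathway_frame(shared, de_enr, dec_enr, core)
    pathway_table_path = outdir / "pathway_table.tsv"
    write_pathway_table(pathway_table, pathway_table_path, header)
    _done("enrichment", t0)

    # -- core-set validation ---------------------------------------------
    t0 = _stage("coreset")
    coreset_path = outdir / "coreset_comparison.tsv"
    if core:
        comp = core_set_comparison(
            de_enr, dec_enr, core, n_draws=config.coreset_draws, seed=seeds["coreset"]
        )
        write_report(
            [
                {
                    "S_de": comp.s_de,
                    "S_dec": comp.s_dec,
                    "D": comp.d,
                    "p_perm": comp.p_perm,
                    "n_draws": comp.n_draws,
                    "core_size": comp.core_size,
                }
            ],
            coreset_path,
            header,
        )
    else:
        write_report(
            [{"S_de": "NA", "S_dec": "NA", "D": "NA", "p_perm": "NA",
              "n_draws": 0, "core_size": 0}],
            coreset_path,
            header,
        )
    _done("coreset", t0)

    return {
        "gene_table": gene_table_path,
        "pathway_table": pathway_table_path,
        "degree_report": degree_report_path,
        "interplay_report": interplay_path,
        "coreset_comparison": coreset_path,
    }


def _pathway_frame(names, de_enr, dec_enr, core):
    import pandas as pd

    p_de = de_enr.p_by_name()
    fdr_de = dict(zip(de_enr.names, de_enr.fdr))
    p_dec = dec_enr.p_by_name()
    fdr_dec = dict(zip(dec_enr.names, dec_enr.fdr))
    core_set = set(core)
    return pd.DataFrame(
        {
            "pathway name": names,
            "p-value DE": [p_de[n] for n in names],
            "FDR DE": [fdr_de[n] for n in names],
            "p-value DEC": [p_dec[n] for n in names],
            "FDR DEC": [fdr_dec[n] for n in names],
            "core set": [int(n in core_set) for n in names],
        }
    )
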