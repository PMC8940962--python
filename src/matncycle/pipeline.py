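"""Run-all orchestration: simulation -> qPCR profiling -> nitrogen coverage
-> community statistics -> HAO classification, with a reproducible report.

Every stage writes its artifacts before the next starts, and a failure in
one stage is recorded in the report without corrupting completed outputs.
Rerunning the same configuration reproduces every numeric output exactly
(the report timestamp is the only field that differs).
"""
from __future__ import annotations

import datetime
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community_stats as cs
from . import hao_motif_phylo as hao
from . import nitrogen_coverage as nc
from . import qpcr_profiles as qp
from . import synthetic_data as sd
from .io import FLOAT_FMT, QPCR_SCHEMA, read_table, write_fasta, write_table

log = logging.getLogger("matncycle")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "matncycle_out"
    simulate: bool = True
    qpcr_path: str | None = None
    annotation_path: str | None = None
    coverage_path: str | None = None
    env_path: str | None = None
    query_fasta: str | None = None
    basis: str = "per_g"
    aggregation: str = "mean"
    alpha: float = 0.05
    n_permutations: int = 999
    nmds_restarts: int = 50
    noise_sd_log10: float = 0.15

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self):
        if not self.simulate:
            missing = [
                name
                for name, p in [
                    ("qpcr_path", self.qpcr_path),
                    ("annotation_path", self.annotation_path),
                    ("coverage_path", self.coverage_path),
                ]
                if p is None or not Path(p).exists()
            ]
            if missing:
                raise ValueError(f"missing input path(s): {missing}")


@dataclass
class RunReport:
    config: dict
    versions: dict
    stages: dict = field(default_factory=dict)
    timestamp: str = ""


def _versions() -> dict:
    import Bio
    import scipy
    import sklearn

    from . import __version__

    return {
        "matncycle": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "biopython": Bio.__version__,
    }


def _round17(obj):
    if isinstance(obj, float):
        return float(f"{obj:.17g}")
    if isinstance(obj, dict):
        return {k: _round17(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round17(v) for v in obj]
    return obj


def _dendrogram_json(node: cs.DendrogramNode):
    return {
        "members": list(node.members),
        "height": node.height,
        "simprof_pi": node.simprof_pi,
        "simprof_p": node.simprof_p,
        "significant": node.significant,
        "children": [_dendrogram_json(c) for c in node.children],
    }


def run_all(config: PipelineConfig) -> RunReport:
    """Execute every stage in dependency order; see module docstring."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config), versions=_versions())

    state: dict = {}

    def stage(name, fn):
        caught: list[str] = []
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                outputs = fn()
            caught = [str(w.message) for w in wlist]
            report.stages[name] = {
                "status": "ok",
                "outputs": outputs,
                "warnings": caught,
            }
            log.info("stage %s: ok", name)
        except Exception as exc:  # stage isolation: later stages may still run
            report.stages[name] = {"status": "failed", "error": repr(exc)}
            log.error("stage %s failed: %r", name, exc)

    def do_inputs():
        if config.simulate:
            simcfg = sd.SimConfig(seed=config.seed, noise_sd_log10=config.noise_sd_log10)
            qpcr, qtruth = sd.simulate_qpcr_panel(simcfg)
            ann, cov, _ = sd.simulate_gene_catalog_and_coverage(simcfg)
            env = sd.make_env_fixture()
            queries, ptruth = sd.generate_hao_proteins(simcfg)
            indir = out / "inputs"
            indir.mkdir(exist_ok=True)
            write_table(qpcr, indir / "qpcr.tsv")
            write_table(ann, indir / "annotations.tsv")
            write_table(cov, indir / "coverage.tsv")
            write_table(env, indir / "environment.tsv")
            write_fasta(queries, indir / "hao_queries.faa")
            with open(indir / "truth.json", "w") as fh:
                json.dump(
                    _round17(
                        {
                            "hao_labels": ptruth.hao_labels,
                            "qpcr_mean_log10": qtruth.qpcr_mean_log10.to_dict("records"),
                        }
                    ),
                    fh,
                    indent=1,
                    sort_keys=True,
                )
            state.update(qpcr=qpcr, ann=ann, cov=cov, env=env, queries=queries)
            return ["inputs/" + f for f in
                    ("qpcr.tsv", "annotations.tsv", "coverage.tsv",
                     "environment.tsv", "hao_queries.faa", "truth.json")]
        state["qpcr"] = read_table(config.qpcr_path, QPCR_SCHEMA)
        state["ann"] = pd.read_csv(config.annotation_path, sep="\t")
        state["cov"] = pd.read_csv(config.coverage_path, sep="\t")
        state["env"] = (
            pd.read_csv(config.env_path, sep="\t") if config.env_path else None
        )
        state["queries"] = (
            __import__("matncycle.io", fromlist=["read_fasta"]).read_fasta(
                config.query_fasta
            )
            if config.query_fasta
            else []
        )
        return []

    def do_qpcr():
        normalized = qp.normalize_copies(state["qpcr"])
        ratios = qp.expression_ratio(
            normalized, basis=config.basis, aggregation=config.aggregation
        )
        value_col = {"per_g": "copies_per_g", "per_ng": "copies_per_ng"}[config.basis]
        screen = qp.shapiro_wilk_screen(
            {
                m: g[value_col].to_numpy()
                for m, g in normalized[~normalized["below_lod"]].groupby("marker")
            }
        )
        results = qp.test_layer_differences(
            normalized, value_col=value_col, template="DNA", alpha=config.alpha
        )
        write_table(normalized, out / "qpcr_normalized.tsv")
        write_table(ratios, out / "qpcr_ratios.tsv")
        write_table(screen, out / "shapiro_screen.tsv")
        tests = {
            r.marker: _round17(
                {
                    "H": r.H,
                    "p_global": r.p_global,
                    "letters": {str(k): v for k, v in r.letters.items()},
                }
            )
            for r in results
        }
        with open(out / "qpcr_tests.json", "w") as fh:
            json.dump(tests, fh, indent=1, sort_keys=True)
        letters = pd.DataFrame(
            [
                (r.marker, layer, letter)
                for r in results
                for layer, letter in sorted(r.letters.items())
            ],
            columns=["marker", "layer", "letters"],
        )
        write_table(letters, out / "qpcr_letters.tsv")
        state["ratios"] = ratios
        return ["qpcr_normalized.tsv", "qpcr_ratios.tsv", "shapiro_screen.tsv",
                "qpcr_tests.json", "qpcr_letters.tsv"]

    def do_ncoverage():
        nitrogen = nc.filter_nitrogen_genes(state["ann"])
        ncpm = nc.compute_ncpm(state["cov"], nitrogen)
        fdic, all_zero = nc.compute_fdic(ncpm)
        summary = nc.pathway_summary(nitrogen)
        write_table(nitrogen, out / "nitrogen_genes.tsv")
        write_table(ncpm, out / "ncpm.tsv")
        write_table(fdic, out / "fdic.tsv")
        fix_ids = nitrogen.loc[
            nitrogen["category"] == "nitrogen fixation", "gene_id"
        ].tolist()
        layers = sorted(ncpm["layer"].unique())
        trend = (
            nc.depth_trend(ncpm, fix_ids, layers[0], layers[-1]) if fix_ids else None
        )
        with open(out / "pathway_summary.json", "w") as fh:
            json.dump(
                _round17(
                    {
                        "per_symbol": summary.per_symbol,
                        "per_category": summary.per_category,
                        "total": summary.total,
                        "shared_note": summary.shared_note,
                        "all_zero_genes": all_zero,
                        "fixation_fold_first_to_last": trend[0] if trend else None,
                        "fixation_direction": trend[1] if trend else None,
                    }
                ),
                fh,
                indent=1,
                sort_keys=True,
            )
        state["ncpm"] = ncpm
        return ["nitrogen_genes.tsv", "ncpm.tsv", "fdic.tsv", "pathway_summary.json"]

    def do_community():
        ratios = state["ratios"]
        mat = ratios.pivot_table(
            index="layer", columns="marker", values="ratio_cdna_dna"
        )
        mat = mat.dropna(axis=0, how="any")
        mat.index = [f"Layer{i}" for i in mat.index]
        if len(mat) < 3:
            raise ValueError("fewer than 3 layers with complete ratio profiles")
        std = cs.standardize_samples(mat)
        sim = cs.bray_curtis(std)
        tree = cs.cluster_group_average(sim)
        cs.simprof(
            std, tree, n_permutations=config.n_permutations,
            alpha=config.alpha, seed=config.seed,
        )
        ord_result = cs.nmds(
            sim, n_restarts=config.nmds_restarts, seed=config.seed
        )
        env = state.get("env")
        env_vars = None
        if env is not None:
            env_vars = env.set_index("layer")[["nh4_um", "no3_um", "po4_um"]]
            env_vars.index = [f"Layer{i}" for i in env_vars.index]
            env_vars = env_vars.loc[env_vars.index.intersection(mat.index)]
        corr = cs.spearman_matrix(
            mat, env_vars.loc[mat.index] if env_vars is not None else None
        )
        overlay = cs.vector_overlay(
            ord_result, mat.join(env_vars, how="left") if env_vars is not None else mat
        )
        write_table(sim.reset_index(names="sample"), out / "resemblance.tsv")
        with open(out / "dendrogram.json", "w") as fh:
            json.dump(_round17(_dendrogram_json(tree)), fh, indent=1, sort_keys=True)
        with open(out / "dendrogram.nwk", "w") as fh:
            fh.write(tree.to_newick() + "\n")
        coords = ord_result.coordinates.reset_index(names="sample")
        coords["stress"] = ord_result.stress
        write_table(coords, out / "nmds_coordinates.tsv")
        write_table(corr, out / "spearman.tsv")
        write_table(overlay, out / "nmds_vectors.tsv")

        # layer structure of the metagenome nitrogen profile (N-CPM)
        ncpm = state["ncpm"]
        prof = ncpm.pivot_table(index="layer", columns="gene_id", values="ncpm").fillna(0.0)
        prof.index = [f"Layer{i}" for i in prof.index]
        mtree = cs.cluster_group_average(cs.bray_curtis(prof))
        cs.simprof(
            prof, mtree, n_permutations=config.n_permutations,
            alpha=config.alpha, seed=config.seed,
        )
        with open(out / "ncpm_dendrogram.json", "w") as fh:
            json.dump(_round17(_dendrogram_json(mtree)), fh, indent=1, sort_keys=True)
        with open(out / "ncpm_dendrogram.nwk", "w") as fh:
            fh.write(mtree.to_newick() + "\n")
        return ["resemblance.tsv", "dendrogram.json", "dendrogram.nwk",
                "nmds_coordinates.tsv", "spearman.tsv", "nmds_vectors.tsv",
                "ncpm_dendrogram.json", "ncpm_dendrogram.nwk"]

    def do_hao():
        queries = state.get("queries") or []
        if not queries:
            return []
        calls, tree, clades = hao.classify_hao_sequences(queries)
        write_table(calls, out / "hao_calls.tsv")
        with open(out / "hao_tree.nwk", "w") as fh:
            fh.write(tree.newick + "\n")
        write_table(
            pd.DataFrame(sorted(clades.items()), columns=["leaf", "clade"]),
            out / "hao_clades.tsv",
        )
        return ["hao_calls.tsv", "hao_tree.nwk", "hao_clades.tsv"]

    stage("inputs", do_inputs)
    if report.stages["inputs"]["status"] == "ok":
        stage("qpcr_profiles", do_qpcr)
        stage("nitrogen_coverage", do_ncoverage)
        if (
            report.stages.get("qpcr_profiles", {}).get("status") == "ok"
            and report.stages.get("nitrogen_coverage", {}).get("status") == "ok"
        ):
            stage("community_stats", do_community)
        stage("hao_motif_phylo", do_hao)

    report.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
    with open(out / "report.json", "w") as fh:
        json.dump(asdict(report), fh, indent=1, sort_keys=True)
    return report
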