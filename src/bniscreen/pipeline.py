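"""End-to-end orchestration: simulate -> preprocess -> stats -> report.

A single :class:`RunConfig` (round-trippable through YAML) governs every
stage.  All tabular outputs are tab-separated UTF-8 with a fixed column
order and a leading comment line carrying the config hash, so two runs
with identical config + seed produce byte-identical files.  The final
consolidated report collects, per strain, the top metabolites from each
evidence stream (Spearman flag, PLS network membership, GA frequency) and
their intersection — the multi-evidence metabolites.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assay import compare_strains
from .assoc import spearman_screen
from .containers import AbundanceMatrix, InhibitionMatrix
from .gadcca import GAConfig, ga_select
from .plsnet import (DEFAULT_EDGE_CUTOFFS, build_network, fit_pls,
                     graph_to_edgelist, plsda_quartiles, relevance_similarity)
from .preprocess import (abundance_balance, pca, quartiles_by_inhibition,
                         venn_membership, volcano)
from .synthetic_data import (StudyDesign, default_truth, make_study,
                             standardized_log_abundance)

__all__ = ["RunConfig", "ConsolidatedReport", "run_pipeline", "evidence_intersection"]


@dataclass
class RunConfig:
    outdir: str = "bni_run"
    seed: int = 0
    # stage toggles
    stages: tuple[str, ...] = (
        "simulate", "preprocess", "assay", "correlate", "plsnet", "gadcca", "report",
    )
    # simulate
    n_genotypes: int = 44
    origin_split: tuple[int, int] = (20, 24)
    n_metabolites: int = 357
    # plsnet
    n_components: int = 2
    edge_cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_EDGE_CUTOFFS))
    plsda_cutoff: float = 0.40
    # gadcca
    ga_repetitions: int = 200
    ga_population: int = 40
    ga_generations: int = 30
    ga_backend: str = "linear-cca"
    # report
    evidence_min_streams: int = 2

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("origin_split", "stages"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def hash(self) -> str:
        """Hash of the scientific configuration (output path excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ConsolidatedReport:
    streams: dict            # strain -> {stream name -> [metabolite, ...]}
    multi_evidence: dict     # strain -> [metabolite, ...]
    manifest: dict


def evidence_intersection(streams: dict[str, list[str]], min_streams: int = 2) -> list[str]:
    """Metabolites present in at least ``min_streams`` evidence streams."""
    if len(streams) < 2:
        raise ValueError("need >= 2 evidence streams")
    counts: dict[str, int] = {}
    for mets in streams.values():
        for m in set(mets):
            counts[m] = counts.get(m, 0) + 1
    return sorted(m for m, c in counts.items() if c >= min_streams)


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = True) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def run_pipeline(cfg: RunConfig) -> ConsolidatedReport:
    """Execute the enabled stages in order, writing every intermediate table."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.hash()
    manifest = {
        "config_hash": h,
        "seed": cfg.seed,
        "version": __version__,
        "stages": list(cfg.stages),
        "stage_seeds": {},
    }
    cfg.to_yaml(out / "config.yaml")

    study = None
    abundance = inhibition = None
    try:
        if "simulate" in cfg.stages:
            design = StudyDesign(
                n_genotypes=cfg.n_genotypes,
                origin_split=tuple(cfg.origin_split),
                n_metabolites=cfg.n_metabolites,
                seed=cfg.seed,
            )
            truth = default_truth(design)
            study = make_study(design, truth)
            abundance, inhibition = study.abundance, study.inhibition
            manifest["stage_seeds"]["simulate"] = cfg.seed
            abundance.write(out / "abundance.tsv", out / "genotype_meta.tsv",
                            out / "metabolite_meta.tsv")
            inhibition.write(out / "inhibition.tsv")
            (out / "truth.json").write_text(json.dumps({
                "active_sets": truth.active_sets,
                "synergy_triplet": list(truth.synergy_triplet or []),
                "synergy_weight": truth.synergy_weight,
                "stimulators": truth.stimulators,
                "origin_shifted": truth.origin_shifted,
                "noise_sd": truth.noise_sd,
            }, indent=2, sort_keys=True))
        else:
            abundance = AbundanceMatrix.read(
                out / "abundance.tsv", out / "genotype_meta.tsv", out / "metabolite_meta.tsv")
            inhibition = InhibitionMatrix.read(out / "inhibition.tsv")
    except (ValueError, FileNotFoundError) as exc:
        raise RuntimeError(f"stage 'simulate/load' failed: {exc}") from exc

    report_streams: dict[str, dict[str, list[str]]] = {}
    strains = inhibition.strains

    if "preprocess" in cfg.stages:
        balanced = abundance_balance(abundance)
        v = volcano(balanced)
        _write_tsv(v.table, out / "volcano.tsv", h)
        _write_tsv(venn_membership(abundance).to_frame(), out / "venn.tsv", h)
        ord_res = pca(balanced, scale=True)
        (out / "pca.json").write_text(json.dumps(
            {"variance_explained": [round(float(x), 10) for x in ord_res.variance_explained[:10]]},
            indent=2))
        q = quartiles_by_inhibition(inhibition)
        _write_tsv(q.labels.to_frame(), out / "quartiles.tsv", h)

    if "assay" in cfg.stages:
        stats_out = {}
        kw = compare_strains(inhibition, grouping="strain")
        stats_out["strain"] = {
            "test": kw.test, "statistic": kw.statistic, "p_value": kw.p_value,
            "letters": kw.group_letters,
        }
        if inhibition.strain_meta is not None:
            wd = compare_strains(inhibition, grouping="domain")
            stats_out["domain"] = {"test": wd.test, "statistic": wd.statistic,
                                   "p_value": wd.p_value, "U": wd.u_statistic}
        reps = inhibition.replicates.copy()
        reps["origin"] = reps["genotype"].map(abundance.genotype_meta["origin"]).values
        wo = compare_strains(InhibitionMatrix(reps, inhibition.strain_meta), grouping="origin")
        stats_out["origin"] = {"test": wo.test, "statistic": wo.statistic,
                               "p_value": wo.p_value, "U": wo.u_statistic}
        (out / "assay_stats.json").write_text(json.dumps(stats_out, indent=2, sort_keys=True))

    if "correlate" in cfg.stages:
        ct = spearman_screen(abundance, inhibition)
        _write_tsv(ct.table.round(10), out / "correlations.tsv", h, index=False)
        for s in strains:
            sub = ct.table[(ct.table["strain"] == s) & (ct.table["flag"] == "positive")]
            report_streams.setdefault(s, {})["spearman"] = list(sub["metabolite"])

    if "plsnet" in cfg.stages:
        z = standardized_log_abundance(abundance)
        for s in strains:
            y = inhibition.strain_vector(s)
            model = fit_pls(z, y.rename(s), n_components=cfg.n_components)
            sim = relevance_similarity(model, z, y.rename(s))
            g = build_network(sim, cfg.edge_cutoffs.get(s, 0.4), abundance.metabolite_meta)
            _write_tsv(graph_to_edgelist(g).round(10), out / f"network_{s}.tsv", h, index=False)
            report_streams.setdefault(s, {})["pls_network"] = sorted(
                n for n in g.nodes if g.nodes[n]["kind"] == "metabolite")
        q = quartiles_by_inhibition(inhibition)
        _, gq, _ = plsda_quartiles(abundance, q, cfg.n_components, cfg.plsda_cutoff)
        _write_tsv(graph_to_edgelist(gq).round(10), out / "network_quartiles.tsv", h, index=False)

    if "gadcca" in cfg.stages:
        ga = GAConfig(population=cfg.ga_population, generations=cfg.ga_generations,
                      repetitions=cfg.ga_repetitions, seed=cfg.seed)
        manifest["stage_seeds"]["gadcca"] = cfg.seed
        for s in strains:
            y = inhibition.strain_vector(s)
            tbl = ga_select(abundance, y, ga, backend=cfg.ga_backend, strain=s)
            out_tbl = tbl.table.copy()
            out_tbl["chemical_class"] = abundance.metabolite_meta["chemical_class"].reindex(out_tbl.index)
            _write_tsv(out_tbl.round(10), out / f"ga_frequency_{s}.tsv", h)
            report_streams.setdefault(s, {})["ga"] = [
                m for m in out_tbl.index[out_tbl["highlighted"]]]

    multi = {}
    if "report" in cfg.stages and report_streams:
        for s, streams in report_streams.items():
            if len(streams) >= 2:
                multi[s] = evidence_intersection(streams, cfg.evidence_min_streams)
        (out / "report.json").write_text(json.dumps(
            {"streams": report_streams, "multi_evidence": multi, "manifest": manifest},
            indent=2, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ConsolidatedReport(report_streams, multi, manifest)
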