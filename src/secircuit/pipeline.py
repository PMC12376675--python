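"""End-to-end orchestration: simulate -> SE call -> stratify -> DE -> circuit
-> survival -> synergy, with a reproducibility manifest.

Each stage reads only the artifacts of earlier stages, writes its outputs
under its own subdirectory, and records a SHA-256 digest per file, so an
identical (config, seed) pair reproduces byte-identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import circuit_finder, drug_response, element_annotation
from . import enrichment_survival, expression_de, se_caller, synthetic_data
from .errors import StageError
from .intervals import compare_peak_sets, write_bed

log = logging.getLogger("secircuit")

STAGE_ORDER = ("simulate", "call_se", "stratify", "de", "circuit",
               "survival", "synergy")


@dataclass
class RunConfig:
    """All pipeline thresholds and sizes in one serializable object."""

    seed: int = 0
    stages: Tuple[str, ...] = STAGE_ORDER
    # synthetic data
    n_genes: int = 5000
    n_chroms: int = 4
    n_background_elements: int = 950
    n_samples_a: int = 4
    n_samples_b: int = 4
    n_patient_samples: int = 13
    n_survival_samples: int = 200
    dispersion: float = 0.01
    expr_effect: float = 1.0
    corr_r: float = 0.8
    hazard_ratio: float = 4.0
    doses_uM: Tuple[float, ...] = (0.5, 1, 2, 5, 10, 20, 50)
    fa_noise_sd: float = 0.0
    # SE calling
    stitch_gap: int = 12_000
    # DE
    lfc_threshold: float = 0.584
    p_threshold: float = 0.05
    # circuit
    r_min: float = 0.5
    p_max: float = 0.05
    min_circuit_size: int = 3
    # survival
    band: Tuple[float, float] = (0.10, 0.90)
    ssgsea_alpha: float = 0.25
    maxstat_n_perm: int = 499
    # enrichment
    gsea_weight_p: float = 1.0

    def validate(self) -> None:
        from .errors import InvalidParameterError
        if not set(self.stages) <= set(STAGE_ORDER):
            raise InvalidParameterError(f"unknown stage in {self.stages}")
        if self.stitch_gap < 0 or not (0 <= self.p_threshold <= 1):
            raise InvalidParameterError("threshold outside its domain")
        if not (-1 <= self.r_min <= 1) or not (0 <= self.p_max <= 1):
            raise InvalidParameterError("circuit threshold outside its domain")
        if not (0 <= self.band[0] < self.band[1] <= 1):
            raise InvalidParameterError("quantile band must satisfy 0<=lo<hi<=1")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        for key in ("stages", "doses_uM", "band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _digest_dir(d: Path) -> Dict[str, str]:
    return {p.name: _sha256(p) for p in sorted(d.iterdir()) if p.is_file()}


def run_pipeline(config: RunConfig, outdir) -> Dict:
    """Execute the enabled stages in dependency order; return the run report.

    Raises :class:`StageError` when an enabled stage's inputs were neither
    produced by an earlier enabled stage nor already present on disk.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: Dict = {"config": dataclasses.asdict(config), "stages": {}}
    state: Dict = {}

    def stage_dir(name: str) -> Path:
        d = outdir / name
        d.mkdir(exist_ok=True)
        return d

    def finish(name: str, t0: float, d: Path, **extra) -> None:
        report["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "digests": _digest_dir(d), **extra}
        log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

    enabled = [s for s in STAGE_ORDER if s in config.stages]

    for name in enabled:
        t0 = time.perf_counter()

        if name == "simulate":
            d = stage_dir("simulate")
            per_chrom = -(-config.n_genes // config.n_chroms)
            chrom_length = max(10_000_000, per_chrom * 110_000)
            ann = synthetic_data.generate_annotation(
                config.n_genes, config.n_chroms, config.seed,
                chrom_length=chrom_length)
            truth = synthetic_data.make_manifest(
                ann, seed=config.seed, expr_effect=config.expr_effect,
                corr_r=config.corr_r, hazard_ratio=config.hazard_ratio)
            epi = synthetic_data.generate_epigenome(
                truth, ann, config.n_background_elements)
            counts, lengths, patient = synthetic_data.generate_expression(
                truth, config.n_samples_a, config.n_samples_b,
                config.n_patient_samples, config.dispersion)
            _, _, cohort = synthetic_data.generate_expression(
                dataclasses.replace(truth, seed=truth.seed + 7),
                config.n_samples_a, config.n_samples_b,
                config.n_survival_samples, config.dispersion)
            # generator-side signature score: standardized circuit-TF mean
            circ = cohort.loc[truth.circuit_tfs]
            z = (circ.sub(circ.mean(axis=1), axis=0)
                     .div(circ.std(axis=1), axis=0)).mean(axis=0)
            surv = synthetic_data.generate_survival(z, truth,
                                                    seed=config.seed + 11)
            dose = synthetic_data.generate_dose_response(
                truth.drug_params, config.fa_noise_sd, config.doses_uM,
                seed=config.seed + 13)
            ann.to_csv(d / "annotation.tsv", sep="\t", index=False)
            truth.to_json(d / "truth.json")
            epi.write(d)
            counts.to_csv(d / "counts.tsv", sep="\t")
            lengths.to_frame().to_csv(d / "lengths.tsv", sep="\t")
            patient.to_csv(d / "patient_expr.tsv", sep="\t")
            cohort.to_csv(d / "survival_expr.tsv", sep="\t")
            surv.to_csv(d / "survival.tsv", sep="\t", index=False)
            for key, df in dose.items():
                df.to_csv(d / f"dose_{key}.tsv", sep="\t", index=False)
            state.update(ann=ann, truth=truth, epi=epi, counts=counts,
                         lengths=lengths, patient=patient, cohort=cohort,
                         surv=surv, dose=dose)
            finish(name, t0, d, n_elements=len(epi.element_table))

        elif name == "call_se":
            if "epi" not in state:
                raise StageError("call_se requires the simulate stage outputs")
            d = stage_dir("call_se")
            epi, ann = state["epi"], state["ann"]
            comparison = compare_peak_sets(epi.h3k27ac_a, epi.h3k27ac_b)
            result = se_caller.call_superenhancers(
                comparison.b_specific, epi.signal_b, gap=config.stitch_gap)
            frame = result.to_frame()
            # SE-driven gene: nearest TSS to the stitched span midpoint
            genes = []
            ann_idx = {c: g.sort_values("tss") for c, g in state["ann"].groupby("chrom")}
            for e in result.enhancers:
                sub = ann_idx.get(e.span.chrom)
                if sub is None:
                    genes.append("")
                    continue
                i = (sub["tss"] - e.span.midpoint).abs().idxmin()
                genes.append(sub.loc[i, "gene"])
            frame["gene"] = genes
            frame.to_csv(d / "stitched_enhancers.tsv", sep="\t", index=False)
            write_bed(result.super_peakset(), d / "superenhancers.bed")
            se_genes = sorted(set(g for g, e in zip(genes, result.enhancers)
                                  if e.is_super and g))
            (d / "se_genes.txt").write_text("\n".join(se_genes) + "\n")
            state.update(se_result=result, se_genes=se_genes,
                         comparison=comparison)
            finish(name, t0, d, n_super=result.n_super,
                   peak_counts=list(comparison.counts),
                   peak_percentages=[round(p, 2) for p in comparison.percentages])

        elif name == "stratify":
            if "epi" not in state:
                raise StageError("stratify requires the simulate stage outputs")
            if "se_result" not in state:
                raise StageError("stratify requires the call_se stage outputs")
            d = stage_dir("stratify")
            epi = state["epi"]
            elements = element_annotation.classify_elements(
                epi.h3k27ac_b, epi.h3k4me3, epi.h3k4me1, state["ann"])
            element_annotation.stratify_cobinding(elements, epi.tf_peaks)
            fpkm = expression_de.fpkm(state["counts"], state["lengths"])
            b_samples = [s for s in fpkm.columns if s.startswith("B")]
            summaries, tests = element_annotation.group_expression_summary(
                elements, fpkm, b_samples,
                se_peaks=state["se_result"].super_peakset())
            rows = [{"element": f"{el.span.chrom}:{el.span.start}-{el.span.end}",
                     "kind": el.kind, "gene": el.gene,
                     "tss_distance": el.tss_distance,
                     "bound_by": ",".join(el.bound_by), "group": el.group,
                     "se_overlap": el.se_overlap} for el in elements]
            pd.DataFrame(rows).to_csv(d / "elements.tsv", sep="\t", index=False)
            tests.to_csv(d / "group_tests.tsv", sep="\t", index=False)
            summary_rows = [{"kind": s.kind, "group": s.group,
                             "n_elements": s.n_elements, "n_genes": len(s.genes),
                             "mean_log2_expr": (float(np.mean(s.expr_values))
                                                if len(s.expr_values) else np.nan),
                             "se_overlap_fraction": s.se_overlap_fraction}
                            for s in summaries]
            pd.DataFrame(summary_rows).to_csv(d / "group_summary.tsv",
                                              sep="\t", index=False)
            state.update(elements=elements, summaries=summaries,
                         group_tests=tests)
            finish(name, t0, d, n_elements=len(elements))

        elif name == "de":
            if "counts" not in state:
                raise StageError("de requires the simulate stage outputs")
            d = stage_dir("de")
            expr = expression_de.ExpressionMatrix(state["counts"],
                                                  state["lengths"])
            a = [s for s in expr.samples if s.startswith("A")]
            b = [s for s in expr.samples if s.startswith("B")]
            de = expression_de.differential_expression(
                expr, a, b, lfc_threshold=config.lfc_threshold,
                p_threshold=config.p_threshold)
            de.to_csv(d / "de.tsv", sep="\t")
            state["de"] = de
            finish(name, t0, d, n_up=int((de["call"] == "up").sum()),
                   n_down=int((de["call"] == "down").sum()))

        elif name == "circuit":
            for dep, why in (("se_genes", "call_se"), ("de", "de"),
                             ("patient", "simulate")):
                if dep not in state:
                    raise StageError(f"circuit requires the {why} stage outputs")
            d = stage_dir("circuit")
            catalog = state["truth"].circuit_tfs + state["truth"].decoy_tfs
            cands = circuit_finder.select_candidates(
                state["se_genes"], state["de"], catalog)
            selected = [c.gene for c in cands if c.is_candidate]
            net = circuit_finder.build_network(state["patient"].loc[selected])
            circuits = circuit_finder.nominate_circuits(
                net, r_min=config.r_min, p_max=config.p_max,
                min_size=config.min_circuit_size)
            net.to_frame().to_csv(d / "edges.tsv", sep="\t", index=False)
            (d / "circuits.json").write_text(json.dumps(
                [{"members": list(c.members), "min_edge_r": c.min_edge_r,
                  "max_edge_p": c.max_edge_p} for c in circuits], indent=1))
            state.update(candidates=selected, circuits=circuits)
            finish(name, t0, d, n_candidates=len(selected),
                   top_circuit=(list(circuits[0].members) if circuits else []))

        elif name == "survival":
            if "cohort" not in state or "surv" not in state:
                raise StageError("survival requires the simulate stage outputs")
            d = stage_dir("survival")
            signature = (list(state["circuits"][0].members)
                         if state.get("circuits")
                         else state["truth"].circuit_tfs)
            cohort = state["cohort"]
            scores = pd.Series(
                {s: enrichment_survival.ssgsea_score(cohort[s], signature,
                                                     alpha=config.ssgsea_alpha)
                 for s in cohort.columns})
            surv = state["surv"].set_index("sample")
            scores = scores.loc[surv.index]
            cut = enrichment_survival.maxstat_cutpoint(
                scores, surv["time"], surv["event"], band=config.band,
                n_perm=config.maxstat_n_perm, seed=config.seed + 17)
            chi2, logrank_p = enrichment_survival.logrank(
                surv["time"], surv["event"], cut.groups.to_numpy())
            out = surv.copy()
            out["score"] = scores
            out["group"] = cut.groups.to_numpy()
            out.to_csv(d / "survival_scored.tsv", sep="\t")
            (d / "cutpoint.json").write_text(json.dumps({
                "signature": signature, "cutpoint": cut.cutpoint,
                "max_stat": cut.max_stat, "adjusted_p": cut.p,
                "logrank_chi2": chi2, "logrank_p": logrank_p}, indent=1))
            state.update(cutpoint=cut, survival_scores=scores)
            finish(name, t0, d, cutpoint=cut.cutpoint, adjusted_p=cut.p)

        elif name == "synergy":
            if "dose" not in state:
                raise StageError("synergy requires the simulate stage outputs")
            d = stage_dir("synergy")
            dose = state["dose"]
            fit1 = drug_response.median_effect_fit(dose["drug1"]["dose_uM"],
                                                   dose["drug1"]["fa"])
            fit2 = drug_response.median_effect_fit(dose["drug2"]["dose_uM"],
                                                   dose["drug2"]["fa"])
            ci = drug_response.combination_index(fit1, fit2,
                                                 dose["combination"])
            ci.to_csv(d / "fa_ci.tsv", sep="\t", index=False)
            (d / "fits.json").write_text(json.dumps({
                "drug1": {"m": fit1.m, "Dm": fit1.dm, "r2": fit1.r2},
                "drug2": {"m": fit2.m, "Dm": fit2.dm, "r2": fit2.r2},
                "mean_ci": float(ci["ci"].mean())}, indent=1))
            state.update(fits=(fit1, fit2), ci_table=ci)
            finish(name, t0, d, mean_ci=float(ci["ci"].mean()))

    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    state["report"] = report
    return state
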