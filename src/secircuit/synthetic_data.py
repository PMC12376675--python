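"""Synthetic two-condition epigenome / expression / survival / dose-response data.

Every downstream stage of the pipeline is exercised against data produced
here, with the planted structure recorded in a :class:`TruthManifest` so
recovery can be scored exactly:

* a gene annotation on ``chr1..chrN`` with evenly spaced, jittered TSSs;
* H3K27ac peak landscapes for a sensitive condition A and a resistant
  condition B with controllable shared/specific fractions, where planted
  super-enhancer elements draw their stitched signal from a heavy upper tail
  (the hockey-stick the rank/signal curve assumes) and everything else from a
  low-signal background;
* H3K4me3 peaks at promoters, H3K4me1 at enhancers, and three TF peak sets
  placed exactly on the elements the manifest declares bound (plus an
  optional false-positive rate);
* negative-binomial count matrices in which circuit TFs and their targets are
  upregulated in condition B, genes under TF-bound elements carry a baseline
  boost proportional to how many TFs bind them, and a patient-like matrix in
  which the circuit TFs share a latent factor with target pairwise Pearson r;
* exponential survival times with a hazard step at a planted score cutpoint;
* median-effect (Hill-type) dose-response curves for two drugs and a
  fixed-ratio combination consistent with a planted combination index.

All outputs are deterministic for a fixed (manifest, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import GenerationError, InvalidParameterError
from .intervals import GenomicInterval, PeakSet, SignalTrack, write_bed, write_bedgraph

__all__ = [
    "TruthManifest",
    "SignalParams",
    "SyntheticEpigenome",
    "make_manifest",
    "generate_annotation",
    "generate_epigenome",
    "generate_expression",
    "generate_survival",
    "generate_dose_response",
]

TF_NAMES = ("TF1", "TF2", "TF3")


@dataclass
class TruthManifest:
    """Planted ground truth for one synthetic study.

    ``bound_elements`` maps element id -> tuple of TF names bound there;
    ``element_genes`` maps every planted element to its target gene;
    ``se_elements`` are the elements whose stitched H3K27ac signal is drawn
    from the high tail. ``expr_effect`` is the log2 fold-change applied to
    circuit TFs and targets in condition B; ``binding_boost`` the baseline
    log2 shift per bound TF on a gene's mean expression; ``corr_r`` the
    target pairwise Pearson correlation of circuit TFs across patient-like
    samples. ``drug_params`` carries per-drug Hill slope m and median-effect
    dose Dm (µM) plus the planted combination index.
    """

    genes: List[str]
    circuit_tfs: List[str]
    decoy_tfs: List[str]
    target_genes: List[str]
    se_elements: List[str]
    bound_elements: Dict[str, Tuple[str, ...]]
    element_genes: Dict[str, str]
    promoter_elements: List[str]
    expr_effect: float = 1.0
    binding_boost: float = 1.0
    corr_r: float = 0.8
    survival_cutpoint: float = 0.0
    hazard_ratio: float = 4.0
    drug_params: Dict = field(default_factory=lambda: {
        "drug1": {"m": 1.5, "Dm": 9.3},
        "drug2": {"m": 1.2, "Dm": 2.0},
        "ci": 0.6,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        universe = set(self.genes)
        for g in self.circuit_tfs + self.decoy_tfs + self.target_genes:
            if g not in universe:
                raise InvalidParameterError(f"gene {g!r} outside the gene universe")
        element_universe = set(self.element_genes)
        for e in self.se_elements:
            if e not in element_universe:
                raise InvalidParameterError(f"SE element {e!r} has no gene assignment")
        for e, tfs in self.bound_elements.items():
            if e not in element_universe:
                raise InvalidParameterError(f"bound element {e!r} has no gene assignment")
            if not set(tfs) <= set(TF_NAMES):
                raise InvalidParameterError(f"unknown TF in {tfs}")
        if not (0.0 <= self.corr_r < 1.0):
            raise InvalidParameterError("corr_r must be in [0, 1)")
        if self.hazard_ratio <= 0:
            raise InvalidParameterError("hazard_ratio must be > 0")
        for drug in ("drug1", "drug2"):
            if self.drug_params[drug]["Dm"] <= 0:
                raise InvalidParameterError("Dm must be > 0")

    # -- serialization ---------------------------------------------------
    def to_json(self, path) -> None:
        d = asdict(self)
        d["bound_elements"] = {k: list(v) for k, v in d["bound_elements"].items()}
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        d = json.loads(Path(path).read_text())
        d["bound_elements"] = {k: tuple(v) for k, v in d["bound_elements"].items()}
        return cls(**d)

    def n_bound_per_gene(self) -> Dict[str, int]:
        """Max number of TFs bound at any element of each gene."""
        out: Dict[str, int] = {}
        for e, tfs in self.bound_elements.items():
            g = self.element_genes[e]
            out[g] = max(out.get(g, 0), len(tfs))
        return out


def generate_annotation(n_genes: int, n_chroms: int, seed: int,
                        chrom_length: int = 10_000_000) -> pd.DataFrame:
    """Gene/TSS table: evenly spaced TSSs with small jitter, random strand.

    Columns: gene, chrom, strand, tss. TSS positions are strictly increasing
    within each chromosome and spaced widely enough that every planted
    regulatory element is nearest to its own gene.
    """
    if n_genes < 1 or n_chroms < 1:
        raise InvalidParameterError("n_genes and n_chroms must be >= 1")
    rng = np.random.default_rng(seed)
    per = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0)
           for i in range(n_chroms)]
    rows = []
    gi = 0
    for ci, k in enumerate(per):
        if k == 0:
            continue
        spacing = chrom_length // (k + 1)
        jitter = rng.integers(-2000, 2001, size=k)
        for j in range(k):
            tss = (j + 1) * spacing + int(jitter[j])
            rows.append({
                "gene": f"G{gi:04d}",
                "chrom": f"chr{ci + 1}",
                "strand": "+" if rng.random() < 0.5 else "-",
                "tss": tss,
            })
            gi += 1
    return pd.DataFrame(rows, columns=["gene", "chrom", "strand", "tss"])


def make_manifest(annotation: pd.DataFrame, seed: int = 0, *,
                  n_circuit: int = 3, n_decoy: int = 15, n_targets: int = 32,
                  n_bound_per_group: int = 40,
                  expr_effect: float = 1.0, binding_boost: float = 1.0,
                  corr_r: float = 0.8, survival_cutpoint: float = 0.0,
                  hazard_ratio: float = 4.0,
                  drug_params: Optional[Dict] = None) -> TruthManifest:
    """Assemble a manifest over the genes of ``annotation``.

    One super-enhancer element is planted per circuit TF, decoy TF, and
    target gene (so ``n_circuit + n_decoy + n_targets`` SE elements, 50 under
    the defaults). Enhancer elements bound by three / two / one TFs are
    planted on ``n_bound_per_group`` further genes each; circuit-TF elements
    (SE and promoter) are bound by all three TFs, mirroring a mutually
    binding circuit.
    """
    genes = annotation["gene"].tolist()
    need = n_circuit + n_decoy + n_targets + 3 * n_bound_per_group
    if need > len(genes):
        raise InvalidParameterError(
            f"need {need} genes for planted structure, annotation has {len(genes)}")
    rng = np.random.default_rng(seed)
    chosen = list(rng.permutation(genes)[:need])
    i = 0
    circuit = sorted(chosen[i:i + n_circuit]); i += n_circuit
    decoys = sorted(chosen[i:i + n_decoy]); i += n_decoy
    targets = sorted(chosen[i:i + n_targets]); i += n_targets
    trio = chosen[i:i + n_bound_per_group]; i += n_bound_per_group
    dual = chosen[i:i + n_bound_per_group]; i += n_bound_per_group
    solo = chosen[i:i + n_bound_per_group]; i += n_bound_per_group

    element_genes: Dict[str, str] = {}
    bound: Dict[str, Tuple[str, ...]] = {}
    se: List[str] = []
    promoters: List[str] = []

    def new_element(prefix: str, gene: str) -> str:
        eid = f"{prefix}{len(element_genes):04d}"
        element_genes[eid] = gene
        return eid

    for g in circuit:
        eid = new_element("SE", g)
        se.append(eid)
        bound[eid] = TF_NAMES
        pid = new_element("PR", g)
        promoters.append(pid)
        bound[pid] = TF_NAMES
    for g in decoys + targets:
        eid = new_element("SE", g)
        se.append(eid)
        if g in targets:
            bound[eid] = TF_NAMES
    duals = [("TF1", "TF2"), ("TF1", "TF3"), ("TF2", "TF3")]
    for j, g in enumerate(trio):
        bound[new_element("EN", g)] = TF_NAMES
    for j, g in enumerate(dual):
        bound[new_element("EN", g)] = duals[j % 3]
    for j, g in enumerate(solo):
        bound[new_element("EN", g)] = (TF_NAMES[j % 3],)

    return TruthManifest(
        genes=genes, circuit_tfs=circuit, decoy_tfs=decoys, target_genes=targets,
        se_elements=se, bound_elements=bound, element_genes=element_genes,
        promoter_elements=promoters, expr_effect=expr_effect,
        binding_boost=binding_boost, corr_r=corr_r,
        survival_cutpoint=survival_cutpoint, hazard_ratio=hazard_ratio,
        drug_params=drug_params or TruthManifest.__dataclass_fields__["drug_params"].default_factory(),
        seed=seed)


@dataclass
class SignalParams:
    """Signal-scale knobs for the epigenome generator.

    Background stitched signals are uniform on [bg_lo, bg_hi]; planted SE
    elements draw totals from [se_lo, se_hi] (a >= 5x separation by default).
    Fractions split the background elements between the two conditions.
    """

    bg_lo: float = 10.0
    bg_hi: float = 100.0
    se_lo: float = 500.0
    se_hi: float = 5000.0
    frac_shared: float = 0.31
    frac_a_specific: float = 0.30
    tf_false_positive_rate: float = 0.0
    peak_width: Tuple[int, int] = (800, 1500)
    se_constituents: Tuple[int, int] = (2, 3)
    slot_spacing: int = 20_000


@dataclass
class SyntheticEpigenome:
    """All peak sets and signal tracks for one synthetic two-condition study."""

    h3k27ac_a: PeakSet
    h3k27ac_b: PeakSet
    h3k4me3: PeakSet
    h3k4me1: PeakSet
    tf_peaks: Dict[str, PeakSet]
    signal_a: SignalTrack
    signal_b: SignalTrack
    element_table: pd.DataFrame  # element, gene, chrom, start, end, signal, is_se, condition
    bedgraph_records_a: List[tuple]
    bedgraph_records_b: List[tuple]

    def write(self, outdir) -> Dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, ps in [("h3k27ac_A", self.h3k27ac_a), ("h3k27ac_B", self.h3k27ac_b),
                         ("h3k4me3_B", self.h3k4me3), ("h3k4me1_B", self.h3k4me1)]:
            p = outdir / f"{name}.bed"
            write_bed(ps, p)
            paths[name] = str(p)
        for tf, ps in self.tf_peaks.items():
            p = outdir / f"tf_{tf}.bed"
            write_bed(ps, p)
            paths[f"tf_{tf}"] = str(p)
        pa, pb = outdir / "signal_A.bdg", outdir / "signal_B.bdg"
        write_bedgraph(self.bedgraph_records_a, pa)
        write_bedgraph(self.bedgraph_records_b, pb)
        paths["signal_A"], paths["signal_B"] = str(pa), str(pb)
        pt = outdir / "elements.tsv"
        self.element_table.to_csv(pt, sep="\t", index=False)
        paths["elements"] = str(pt)
        return paths


def generate_epigenome(truth: TruthManifest, annotation: pd.DataFrame,
                       n_background_elements: int = 950,
                       params: Optional[SignalParams] = None) -> SyntheticEpigenome:
    """Place planted and background elements on the genome and emit peaks/coverage.

    Each gene owns five element slots (the promoter at the TSS and enhancer
    slots at +/- one and two slot-spacings), keeping every element nearest to
    its own TSS and non-SE elements more than a stitch gap apart. SE elements
    are clusters of 2-3 constituent peaks within a few kb so that stitching
    is exercised; their summed signal comes from the high tail. Per-base
    bedGraph coverage is constant within each peak at signal/width, so the
    sum over a peak equals its assigned signal up to float rounding.
    """
    params = params or SignalParams()
    if params.frac_shared + params.frac_a_specific > 1.0:
        raise InvalidParameterError("shared + A-specific fractions exceed 1")
    rng = np.random.default_rng(truth.seed + 101)
    ann = annotation.set_index("gene")
    spacing = int(params.slot_spacing)

    # slot bookkeeping: (gene, slot) -> taken
    enhancer_slots = [-2, -1, 1, 2]
    taken: set = set()

    def place(gene: str, slot: int, width: int) -> Tuple[str, int, int]:
        row = ann.loc[gene]
        center = int(row.tss) + slot * spacing
        start = max(0, center - width // 2)
        return str(row.chrom), start, start + width

    def pick_slot(gene: str) -> int:
        for s in enhancer_slots:
            if (gene, s) not in taken:
                taken.add((gene, s))
                return s
        raise GenerationError(f"no free enhancer slot at gene {gene}")

    elements = []  # dicts
    wlo, whi = params.peak_width

    # planted elements, in manifest order for determinism
    for eid, gene in truth.element_genes.items():
        if eid in truth.promoter_elements:
            chrom, start, end = place(gene, 0, 800)
            taken.add((gene, 0))
            elements.append(dict(element=eid, gene=gene, chrom=chrom, start=start,
                                 end=end, is_se=False, kind="promoter",
                                 condition="both"))
        elif eid in truth.se_elements:
            slot = pick_slot(gene)
            row = ann.loc[gene]
            base = int(row.tss) + slot * spacing
            k = int(rng.integers(params.se_constituents[0],
                                 params.se_constituents[1] + 1))
            widths = rng.integers(wlo, whi + 1, size=k)
            gaps = rng.integers(200, 1500, size=k)
            pos = base
            cons = []
            for w, g in zip(widths, gaps):
                cons.append((pos, pos + int(w)))
                pos += int(w) + int(g)
            elements.append(dict(element=eid, gene=gene, chrom=str(row.chrom),
                                 start=cons[0][0], end=cons[-1][1], is_se=True,
                                 kind="enhancer", condition="b",
                                 constituents=cons))
        else:
            slot = pick_slot(gene)
            w = int(rng.integers(wlo, whi + 1))
            chrom, start, end = place(gene, slot, w)
            elements.append(dict(element=eid, gene=gene, chrom=chrom, start=start,
                                 end=end, is_se=False, kind="enhancer",
                                 condition="both"))

    # background elements go to genes carrying no planted element, so the
    # gene-level co-binding groups stay uncontaminated
    planted_genes = set(truth.element_genes.values())
    free = [(g, s) for g in annotation["gene"] if g not in planted_genes
            for s in enhancer_slots]
    if n_background_elements > len(free):
        raise GenerationError(
            f"requested {n_background_elements} background elements, "
            f"only {len(free)} free slots")
    order = rng.permutation(len(free))[:n_background_elements]
    n_sh = int(round(params.frac_shared * n_background_elements))
    n_a = int(round(params.frac_a_specific * n_background_elements))
    for j, idx in enumerate(order):
        gene, slot = free[idx]
        taken.add((gene, slot))
        w = int(rng.integers(wlo, whi + 1))
        chrom, start, end = place(gene, slot, w)
        condition = "both" if j < n_sh else ("a" if j < n_sh + n_a else "b")
        elements.append(dict(element=f"BG{j:04d}", gene=gene, chrom=chrom,
                             start=start, end=end, is_se=False, kind="enhancer",
                             condition=condition))

    # placement sanity: H3K27ac elements must not collide (TSS spacing too
    # tight for the slot layout would silently corrupt stitching otherwise)
    placed = sorted(((el["chrom"], el["start"], el["end"], el["element"])
                     for el in elements))
    for (c1, s1, e1, n1), (c2, s2, e2, n2) in zip(placed, placed[1:]):
        if c1 == c2 and s2 < e1:
            raise GenerationError(
                f"element collision between {n1} and {n2} on {c1}; "
                "increase chromosome length or reduce elements per gene")

    # signals per condition; the SE tail is geometrically spread (with jitter)
    # so the ascending rank/signal curve is convex through the tail
    se_idx = [i for i, el in enumerate(elements) if el["is_se"]]
    n_se = len(se_idx)
    if n_se:
        ratio = params.se_hi / params.se_lo
        steps = (np.arange(1, n_se + 1) + rng.uniform(-0.3, 0.3, n_se)) / n_se
        tail = params.se_lo * ratio ** steps
        order = rng.permutation(n_se)
        for j, i in enumerate(se_idx):
            elements[i]["signal_b"] = float(tail[order[j]])
            elements[i]["signal_a"] = 0.0
    for el in elements:
        if el["is_se"]:
            pass
        else:
            sig = float(rng.uniform(params.bg_lo, params.bg_hi))
            el["signal_a"] = sig if el["condition"] in ("both", "a") else 0.0
            el["signal_b"] = sig if el["condition"] in ("both", "b") else 0.0

    # build peak sets and coverage
    def peaks_for(cond_key: str) -> Tuple[PeakSet, List[tuple]]:
        ivs, recs = [], []
        for el in elements:
            sig = el[f"signal_{cond_key}"]
            if sig <= 0:
                continue
            cons = el.get("constituents") or [(el["start"], el["end"])]
            total_w = sum(e - s for s, e in cons)
            for ci, (s, e) in enumerate(cons):
                part = sig * (e - s) / total_w
                name = el["element"] if len(cons) == 1 else f"{el['element']}_{ci}"
                ivs.append(GenomicInterval(el["chrom"], s, e, name, part))
                recs.append((el["chrom"], s, e, part / (e - s)))
        return PeakSet.from_intervals(ivs, label=f"H3K27ac_{cond_key.upper()}"), recs

    h3k27ac_a, recs_a = peaks_for("a")
    h3k27ac_b, recs_b = peaks_for("b")

    # promoter / enhancer marks (condition B landscape)
    me3 = [GenomicInterval(str(r.chrom), max(0, int(r.tss) - 500),
                           int(r.tss) + 500, r.gene)
           for r in annotation.itertuples()]
    me1 = [GenomicInterval(el["chrom"], el["start"], el["end"], el["element"])
           for el in elements
           if el["kind"] == "enhancer" and el["condition"] in ("both", "b")]

    # TF footprints on bound elements (+ optional false positives)
    el_by_id = {el["element"]: el for el in elements}
    tf_ivs: Dict[str, list] = {tf: [] for tf in TF_NAMES}
    for eid, tfs in truth.bound_elements.items():
        el = el_by_id[eid]
        # centre the footprint inside the first constituent peak so the
        # binding overlaps the element's H3K27ac signal even for clusters
        cons = el.get("constituents") or [(el["start"], el["end"])]
        mid = (cons[0][0] + cons[0][1]) // 2
        for tf in tfs:
            tf_ivs[tf].append(GenomicInterval(el["chrom"], max(0, mid - 150),
                                              mid + 150, eid))
    if params.tf_false_positive_rate > 0:
        for tf in TF_NAMES:
            for el in elements:
                eid = el["element"]
                if tf in truth.bound_elements.get(eid, ()):
                    continue
                if rng.random() < params.tf_false_positive_rate:
                    mid = (el["start"] + el["end"]) // 2
                    tf_ivs[tf].append(GenomicInterval(el["chrom"],
                                                      max(0, mid - 150),
                                                      mid + 150, eid))
    tf_peaks = {tf: PeakSet.from_intervals(ivs, label=tf)
                for tf, ivs in tf_ivs.items()}

    table = pd.DataFrame([{k: v for k, v in el.items() if k != "constituents"}
                          for el in elements])
    return SyntheticEpigenome(
        h3k27ac_a=h3k27ac_a, h3k27ac_b=h3k27ac_b,
        h3k4me3=PeakSet.from_intervals(me3, label="H3K4me3"),
        h3k4me1=PeakSet.from_intervals(me1, label="H3K4me1"),
        tf_peaks=tf_peaks,
        signal_a=SignalTrack.from_intervals(recs_a),
        signal_b=SignalTrack.from_intervals(recs_b),
        element_table=table,
        bedgraph_records_a=recs_a, bedgraph_records_b=recs_b)


def generate_expression(truth: TruthManifest, n_samples_a: int, n_samples_b: int,
                        n_patient_samples: int, dispersion: float = 0.05,
                        base_mean_log2: float = 6.0, base_sd_log2: float = 1.0,
                        patient_sd_log2: float = 1.0,
                        ) -> Tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Counts for two cell-line conditions plus a patient-like log2 matrix.

    Counts are gamma-Poisson (negative binomial): variance mu + dispersion *
    mu^2. Gene mean structure: a lognormal baseline, plus ``binding_boost``
    log2 units per TF bound at the gene's elements (both conditions), plus
    ``expr_effect`` log2 units in condition B only for every SE-driven gene
    (circuit TFs, decoy TFs, targets). The patient matrix is on the log2 scale; circuit TFs load on one
    shared latent factor so each pair has Pearson correlation ``corr_r``.

    Returns ``(counts, gene_lengths, patient_matrix)``.
    """
    if n_samples_a < 2 or n_samples_b < 2:
        raise InvalidParameterError("need >= 2 samples per condition")
    if n_patient_samples < 3:
        raise InvalidParameterError("need >= 3 patient-like samples")
    if dispersion <= 0:
        raise InvalidParameterError("dispersion must be > 0")
    rng = np.random.default_rng(truth.seed + 202)
    genes = truth.genes
    n_genes = len(genes)
    base = base_mean_log2 + base_sd_log2 * rng.standard_normal(n_genes)
    n_bound = truth.n_bound_per_gene()
    boost = np.array([truth.binding_boost * n_bound.get(g, 0) for g in genes])
    de_set = set(truth.circuit_tfs) | set(truth.decoy_tfs) | set(truth.target_genes)
    effect = np.array([truth.expr_effect if g in de_set else 0.0 for g in genes])

    mu_a = 2.0 ** (base + boost)
    mu_b = 2.0 ** (base + boost + effect)
    shape = 1.0 / dispersion

    def nb_counts(mu: np.ndarray, n_samples: int) -> np.ndarray:
        lam = rng.gamma(shape, scale=mu[:, None] / shape,
                        size=(n_genes, n_samples))
        return rng.poisson(lam)

    counts = np.hstack([nb_counts(mu_a, n_samples_a), nb_counts(mu_b, n_samples_b)])
    samples = ([f"A{i + 1:02d}" for i in range(n_samples_a)]
               + [f"B{i + 1:02d}" for i in range(n_samples_b)])
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                             columns=samples)
    lengths = pd.Series(rng.integers(500, 5001, size=n_genes),
                        index=counts_df.index, name="length")

    # patient-like matrix (log2 scale)
    r = truth.corr_r
    latent = rng.standard_normal(n_patient_samples)
    noise = rng.standard_normal((n_genes, n_patient_samples))
    circuit_mask = np.array([g in set(truth.circuit_tfs) for g in genes])
    z = noise.copy()
    z[circuit_mask] = (np.sqrt(r) * latent
                       + np.sqrt(1.0 - r) * noise[circuit_mask])
    patient = (base + boost + effect)[:, None] + patient_sd_log2 * z
    patient_df = pd.DataFrame(
        patient, index=counts_df.index,
        columns=[f"P{i + 1:03d}" for i in range(n_patient_samples)])
    return counts_df, lengths, patient_df


def generate_survival(scores: pd.Series, truth: TruthManifest, seed: int,
                      censoring_rate: float = 0.1,
                      baseline_hazard: float = 0.1) -> pd.DataFrame:
    """Exponential event times with a hazard step at the planted cutpoint.

    Samples with score > ``truth.survival_cutpoint`` have their hazard
    multiplied by ``truth.hazard_ratio``. Censoring times are independent
    exponentials tuned so the low-score group is censored at roughly
    ``censoring_rate``. Columns: sample, time, event, true_group.
    """
    scores = pd.Series(scores)
    if scores.empty:
        raise InvalidParameterError("scores must be non-empty")
    if not np.all(np.isfinite(scores.to_numpy(dtype=float))):
        raise InvalidParameterError("scores must be finite")
    if not (0.0 <= censoring_rate < 1.0):
        raise InvalidParameterError("censoring_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    high = scores.to_numpy(dtype=float) > truth.survival_cutpoint
    hazard = baseline_hazard * np.where(high, truth.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if censoring_rate > 0:
        c_rate = baseline_hazard * censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=scores.size)
    else:
        t_cens = np.full(scores.size, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({
        "sample": scores.index.astype(str),
        "time": time,
        "event": event,
        "true_group": np.where(high, "high", "low"),
    })


def _median_effect_fa(dose: np.ndarray, m: float, dm: float) -> np.ndarray:
    return 1.0 / (1.0 + (dm / dose) ** m)


def generate_dose_response(drug_params: Dict, fa_noise_sd: float,
                           doses: Sequence[float], seed: int,
                           ) -> Dict[str, pd.DataFrame]:
    """Hill-type single-agent curves and a fixed-ratio combination.

    Single agents follow the median-effect curve fa = 1/(1 + (Dm/D)^m) with
    optional Gaussian noise on fa (clamped to (0, 1)). Combination rows use a
    fixed dose ratio d2/d1 = Dm2/Dm1; at each row the fraction affected is
    the value at which d1/Dx1(fa) + d2/Dx2(fa) equals the planted combination
    index, so a zero-noise round trip through the synergy fit recovers it.
    Returns {"drug1": ..., "drug2": ..., "combination": ...}.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0 or np.any(doses <= 0):
        raise InvalidParameterError("doses must be positive")
    if not (0.0 <= fa_noise_sd < 0.2):
        raise InvalidParameterError("fa_noise_sd must be in [0, 0.2)")
    rng = np.random.default_rng(seed)
    ci = float(drug_params["ci"])
    out: Dict[str, pd.DataFrame] = {}
    for key in ("drug1", "drug2"):
        m, dm = float(drug_params[key]["m"]), float(drug_params[key]["Dm"])
        fa = _median_effect_fa(doses, m, dm)
        if fa_noise_sd > 0:
            fa = np.clip(fa + rng.normal(0.0, fa_noise_sd, size=fa.size),
                         1e-4, 1 - 1e-4)
        out[key] = pd.DataFrame({"dose_uM": doses, "fa": fa})

    m1, dm1 = float(drug_params["drug1"]["m"]), float(drug_params["drug1"]["Dm"])
    m2, dm2 = float(drug_params["drug2"]["m"]), float(drug_params["drug2"]["Dm"])
    ratio = dm2 / dm1
    rows = []
    for d in doses:
        d1, d2 = d, d * ratio

        def excess(fa: float) -> float:
            dx1 = dm1 * (fa / (1 - fa)) ** (1.0 / m1)
            dx2 = dm2 * (fa / (1 - fa)) ** (1.0 / m2)
            return d1 / dx1 + d2 / dx2 - ci

        fa = brentq(excess, 1e-12, 1 - 1e-12)
        if fa_noise_sd > 0:
            fa = float(np.clip(fa + rng.normal(0.0, fa_noise_sd), 1e-4, 1 - 1e-4))
        rows.append({"d1_uM": d1, "d2_uM": d2, "fa": fa})
    out["combination"] = pd.DataFrame(rows)
    return out
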