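"""Shared fixtures: a desk-scale synthetic study generated once per session."""

import numpy as np
import pandas as pd
import pytest

from secircuit import synthetic_data as syn


@pytest.fixture(scope="session")
def small_annotation() -> pd.DataFrame:
    # 240 genes on 2 chromosomes, TSS spacing ~110 kb (safe for the slot layout)
    return syn.generate_annotation(240, 2, seed=7, chrom_length=13_500_000)


@pytest.fixture(scope="session")
def big_annotation() -> pd.DataFrame:
    # transcriptome-scale universe so planted DE genes are a small fraction
    return syn.generate_annotation(5000, 4, seed=11,
                                   chrom_length=110_000 * 1250)


@pytest.fixture(scope="session")
def small_truth(small_annotation) -> syn.TruthManifest:
    return syn.make_manifest(small_annotation, seed=7, n_targets=12,
                             n_bound_per_group=15)


@pytest.fixture(scope="session")
def small_epigenome(small_truth, small_annotation) -> syn.SyntheticEpigenome:
    return syn.generate_epigenome(small_truth, small_annotation,
                                  n_background_elements=200)


@pytest.fixture(scope="session")
def small_expression(small_truth):
    counts, lengths, patient = syn.generate_expression(
        small_truth, n_samples_a=4, n_samples_b=4, n_patient_samples=13,
        dispersion=0.01)
    return counts, lengths, patient
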