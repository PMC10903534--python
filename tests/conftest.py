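"""Shared fixtures: hand-built variant tables and a small simulated cohort."""

import numpy as np
import pytest

from introscan import FrequencyTable, SimConfig, VariantTable, simulate


def make_variant_table(chrom, pos, gt, samples=None, qual=None, depth=None, gq=None):
    """Build a VariantTable from plain lists (gt rows = sites)."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    if samples is None:
        samples = [f"s{j}" for j in range(n_samples)]
    return VariantTable(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        qual=np.full(n_sites, 100.0) if qual is None else np.asarray(qual, float),
        samples=list(samples),
        gt=gt,
        depth=None if depth is None else np.asarray(depth, np.int32),
        gq=None if gq is None else np.asarray(gq, np.float32),
    )


def make_freq_table(chrom, pos, pops, freq, n=None, miss=None):
    freq = np.asarray(freq, dtype=float)
    if n is None:
        n = np.full(freq.shape, 40, dtype=np.int32)
    if miss is None:
        miss = np.zeros(freq.shape)
    return FrequencyTable(
        np.asarray(chrom, dtype=object), np.asarray(pos, dtype=np.int64),
        list(pops), freq, np.asarray(n, np.int32), np.asarray(miss, float),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated cohort shared by read-only tests."""
    cfg = SimConfig(seed=42, n_sites=30_000)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_freqs(small_sim):
    from introscan import allele_frequencies

    return allele_frequencies(small_sim.vt, small_sim.popmap)
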