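"""Shared fixtures: small synthetic datasets generated at test time."""

import math

import pytest

from pasfinder import synthetic


def oracle_detect_tail(seq, side, base, min_run=10, mismatch_fraction=0.10):
    """Exhaustive terminal-substring oracle for tail detection.

    Enumerates every end-anchored window, applies the mismatch budget,
    end-on-base rules and the minimum-run threshold, and returns the
    longest qualifying (length, mismatches) or None.  Independent of the
    incremental scan used by the implementation.
    """
    seq = seq.upper()
    n = len(seq)
    best = None
    for length in range(1, n + 1):
        window = seq[n - length :] if side == "3prime" else seq[:length]
        inner = window[0] if side == "3prime" else window[-1]
        outer = window[-1] if side == "3prime" else window[0]
        mm = sum(1 for ch in window if ch != base)
        if (
            length >= min_run
            and inner == base
            and outer == base
            and mm <= math.floor(mismatch_fraction * length)
        ):
            best = (length, mm)
    return best


@pytest.fixture(scope="session")
def small_dataset():
    """60 kb genome, 5 genes with 1-3 PAS each, 3 decoy loci, seed 1."""
    truth, gtf = synthetic.make_dataset(
        genome_length=60_000,
        n_genes=5,
        n_decoys=3,
        pas_per_gene=(1, 3),
        utr_pas_spacing=300,
        seed=1,
    )
    return truth, gtf


@pytest.fixture(scope="session")
def small_reads(small_dataset):
    truth, _ = small_dataset
    return synthetic.simulate_reads(truth, reads_per_pas=5, n_decoy_reads=9, seed=3)
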