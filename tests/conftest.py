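"""Shared toy genomes and synthetic fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from biallelic.spectra import (
    CHANNEL_OF,
    ContextGenome,
    MutationRecord,
    TrinucleotideSpectrum,
)


@pytest.fixture(scope="session")
def toy_genome() -> ContextGenome:
    """A 60 bp handcrafted genome, fully callable."""
    seq = (
        "ACATGCATGACGTACGTACGATCGATCGTAGCTAGCATGCATGCACATGACGTGCATGCA"
    )
    return ContextGenome({"chr1": seq}, {"chr1": [(0, len(seq))]})


def ct_alphabet_genome(n_loci: int, seed: int = 5) -> ContextGenome:
    """Random genome over {C, T} with ``n_loci`` mutable positions.

    Every position is equally mutable under a C>T/T>C spectrum and the
    mutation alphabet is closed, so back mutations are representable and the
    hit process is uniform over loci — the setting of the birthday closed
    form.
    """
    rng = np.random.default_rng(seed)
    length = n_loci + 2
    seq = "".join(rng.choice(["C", "T"], size=length))
    return ContextGenome({"chr1": seq}, {"chr1": [(0, length)]})


def ct_alphabet_spectrum(genome: ContextGenome) -> TrinucleotideSpectrum:
    """Spectrum with C>T and T>C mass proportional to context abundance."""
    f = genome.channel_abundance().astype(float)
    counts = np.zeros(96)
    for (tri, alt), ch in CHANNEL_OF.items():
        if set(tri) <= {"C", "T"} and (
            (tri[1] == "C" and alt == "T") or (tri[1] == "T" and alt == "C")
        ):
            counts[ch] = f[ch]
    return TrinucleotideSpectrum(counts).normalise()


def block_toy_genome(
    block_kinds: np.ndarray,
) -> ContextGenome:
    """Tiled 5 bp blocks with isolated mutable centres.

    ``block_kinds`` selects per block between an A[C_]A context (TACAT) and a
    G[C_]G context (TGCGT); callable windows cover only the centre
    trinucleotide, so each block contributes exactly one mutable locus.
    """
    blocks = ["TACAT" if k else "TGCGT" for k in block_kinds]
    intervals = [(5 * i + 1, 5 * i + 4) for i in range(len(blocks))]
    return ContextGenome({"chr1": "".join(blocks)}, {"chr1": intervals})


def single_channel_catalog(
    genome: ContextGenome, channel_tri: str, alt: str, n: int, seed: int
) -> list[MutationRecord]:
    """Catalog of n mutations all in one channel, at distinct loci."""
    rng = np.random.default_rng(seed)
    positions = genome.callable_positions("chr1")
    seq = genome.sequences["chr1"]
    eligible = [
        int(p) for p in positions if seq[p - 1 : p + 2] == channel_tri
    ]
    chosen = rng.choice(len(eligible), size=n, replace=False)
    return [
        MutationRecord("chr1", eligible[i] + 1, channel_tri[1], (alt,))
        for i in chosen
    ]
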