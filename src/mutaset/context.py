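"""Local sequence context around substitutions.

Two views of context: (1) positional nucleotide composition of k-mers
(default 7-mers) centred on each mutation, compared with k-mers sampled
uniformly from the genome; (2) the 96-channel single-base-substitution
spectrum in the COSMIC pyrimidine-centred convention, with cosine
similarity to supplied reference signatures.  A simple length-weighted
random-mutation model provides the comparator for sequence-length plots.

k-mers are taken on the reference strand as-is (the composition figures
show raw A/C/G/T content); the trinucleotide spectrum does collapse
strands per the COSMIC convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import NUCLEOTIDES

_NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Canonical COSMIC channel order: substitution-major, then 5' base, then 3'.
SBS_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
SBS96_CHANNELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SBS_TYPES
    for five in NUCLEOTIDES
    for three in NUCLEOTIDES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(SBS96_CHANNELS)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CompositionMatrix:
    """k x 4 positional A/C/G/T frequencies of aligned k-mers."""

    freq: np.ndarray
    n_kmers: int
    k: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq, columns=list(NUCLEOTIDES))
        offset = (self.k - 1) // 2
        df.insert(0, "position", np.arange(-offset, offset + 1))
        return df


@dataclass
class KmerTally:
    n_skipped_edge: int = 0
    n_skipped_ambiguous: int = 0
    n_ref_mismatch: int = 0


def _composition(kmers: list[str], k: int) -> CompositionMatrix:
    counts = np.zeros((k, 4))
    for km in kmers:
        for i, base in enumerate(km):
            counts[i, _NT_INDEX[base]] += 1
    n = len(kmers)
    freq = counts / n if n else counts
    return CompositionMatrix(freq=freq, n_kmers=n, k=k)


def _fetch_window(genome, chrom: str, pos: int, k: int) -> str | None:
    """Reference-strand window of width k centred on 1-based `pos`; None at
    chromosome edges."""
    half = (k - 1) // 2
    start0 = pos - 1 - half
    end0 = pos + half
    if start0 < 0 or end0 > len(genome[chrom]):
        return None
    return str(genome[chrom][start0:end0]).upper()


def extract_kmers(
    records,
    genome,
    k: int = 7,
    stratify_by_class: bool = False,
    tally: KmerTally | None = None,
):
    """Composition of k-mers centred on each mutation (reference strand).

    Windows crossing a chromosome edge or containing ambiguous bases are
    skipped; records whose ref allele disagrees with the genome base are
    excluded as reference mismatches.  All skips are tallied.  With
    `stratify_by_class` a dict of per-exposure-class matrices is returned.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if tally is None:
        tally = KmerTally()
    kmers_by_stratum: dict[str, list[str]] = {}
    half = (k - 1) // 2
    for r in records:
        window = _fetch_window(genome, r.chrom, r.pos, k)
        if window is None:
            tally.n_skipped_edge += 1
            continue
        if any(b not in _NT_INDEX for b in window):
            tally.n_skipped_ambiguous += 1
            continue
        if window[half] != r.ref_allele:
            tally.n_ref_mismatch += 1
            continue
        key = r.exposure_class if stratify_by_class else "all"
        kmers_by_stratum.setdefault(key, []).append(window)
    if stratify_by_class:
        return {c: _composition(v, k) for c, v in kmers_by_stratum.items()}
    return _composition(kmers_by_stratum.get("all", []), k)


def sample_random_kmers(genome, n: int = 50000, k: int = 7, seed=0) -> CompositionMatrix:
    """Composition of `n` k-mers drawn uniformly over edge-safe,
    ambiguity-free windows of the whole genome."""
    if k % 2 == 0:
        raise ValueError("k must be odd")
    rng = np.random.default_rng(seed)
    chroms = list(genome.keys()) if hasattr(genome, "keys") else [r.name for r in genome]
    lengths = np.array([max(len(genome[c]) - k + 1, 0) for c in chroms], dtype=float)
    if lengths.sum() <= 0:
        raise ValueError("genome has no window of width k")
    probs = lengths / lengths.sum()
    kmers: list[str] = []
    attempts = 0
    max_attempts = 50 * n + 1000
    while len(kmers) < n and attempts < max_attempts:
        attempts += 1
        ci = rng.choice(len(chroms), p=probs)
        start = int(rng.integers(0, int(lengths[ci])))
        km = str(genome[chroms[ci]][start : start + k]).upper()
        if all(b in _NT_INDEX for b in km):
            kmers.append(km)
    if len(kmers) < n:
        raise RuntimeError("could not sample enough ambiguity-free k-mers")
    return _composition(kmers, k)


@dataclass
class SpectrumVector:
    """Counts over the 96 pyrimidine-centred SBS channels."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=int))
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(SBS96_CHANNELS), name="count")


def sbs96_channel(context: str, ref: str, alt: str) -> str:
    """Map a 3-mer reference context and substitution to its COSMIC channel,
    reverse-complementing purine-centred changes to the pyrimidine strand."""
    if len(context) != 3 or context[1] != ref:
        raise ValueError("context must be a 3-mer centred on the ref allele")
    if ref in ("A", "G"):
        context = revcomp(context)
        ref = context[1]
        alt = alt.translate(_COMPLEMENT)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def trinucleotide_spectrum(records, genome) -> SpectrumVector:
    """96-channel spectrum of the records' reference trinucleotide contexts.

    Contexts with ambiguous bases, chromosome-edge positions, or a ref
    allele disagreeing with the genome are excluded and tallied.
    """
    spec = SpectrumVector()
    for r in records:
        ctx = _fetch_window(genome, r.chrom, r.pos, 3)
        if ctx is None or any(b not in _NT_INDEX for b in ctx) or ctx[1] != r.ref_allele:
            spec.n_excluded += 1
            continue
        spec.counts[_CHANNEL_INDEX[sbs96_channel(ctx, r.ref_allele, r.alt_allele)]] += 1
    return spec


def cosine_similarity(spectrum, reference) -> float:
    """Cosine of two non-negative 96-vectors (or any equal-length vectors)."""
    a = np.asarray(spectrum, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("all-zero vector has undefined cosine similarity")
    return float(np.dot(a, b) / (na * nb))


def random_mutation_length_model(lengths, n: int = 100000, seed=0) -> np.ndarray:
    """Lengths of the sequences hit by mutating `n` nucleotides uniformly
    over the concatenation of all target sequences; the hit probability of a
    sequence is proportional to its length (the dashed-comparator model for
    length plots)."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0 or (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    rng = np.random.default_rng(seed)
    hits = rng.choice(lengths, size=n, p=lengths / lengths.sum())
    return hits
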