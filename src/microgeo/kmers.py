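"""Taxonomy-free k-mer features at desk scale.

Instead of assigning reads to taxa against a reference database, each
sample is fingerprinted by the frequencies of its length-k subsequences
(k = 31 by default).  Windows containing an ambiguous symbol (anything
outside A/C/G/T) are skipped; counting is canonical by default, folding
each k-mer onto the lexicographic minimum of itself and its reverse
complement, since shotgun reads come from either strand.  Rare k-mers are
removed per sample (count below a threshold), then the sample x k-mer
matrix is prevalence-filtered (a k-mer must be present in at least 10% of
samples, threshold inclusive) and each row normalised to sum to 1.  The
resulting matrix feeds the same ensemble classifier as the taxonomic path.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from scipy import sparse

from .abundance import LabeledAbundanceTable
from .errors import EmptyResultError, ParseError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def reverse_complement(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _open_maybe_gz(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path) -> str:
    name = Path(path).name.removesuffix(".gz")
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def iter_reads(path):
    """Yield upper-cased read sequences from a FASTA/FASTQ file (gz ok)."""
    fmt = _sniff_format(path)
    with _open_maybe_gz(path) as fh:
        try:
            for i, record in enumerate(SeqIO.parse(fh, fmt)):
                yield str(record.seq).upper()
        except ValueError as exc:
            raise ParseError(f"{path}: malformed {fmt} near record {i}: {exc}") from exc


def count_kmers(path, k: int = 31, min_count: int = 20, canonical: bool = True) -> dict:
    """Count k-mers in one read file, skipping windows with ambiguous bases.

    Returns ``{kmer: count}`` after dropping k-mers whose count is below
    ``min_count``.  With ``canonical`` each window is folded onto the
    lexicographic minimum of (k-mer, reverse complement).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict = {}
    for seq in iter_reads(path):
        n = len(seq)
        # positions of invalid symbols bound the clean stretches
        bad = [i for i, ch in enumerate(seq) if ch not in _VALID]
        starts = [0] + [b + 1 for b in bad]
        ends = bad + [n]
        for s, e in zip(starts, ends):
            for i in range(s, e - k + 1):
                kmer = seq[i:i + k]
                if canonical:
                    kmer = canonical_kmer(kmer)
                counts[kmer] = counts.get(kmer, 0) + 1
    return {kmer: c for kmer, c in counts.items() if c >= min_count}


def count_kmers_per_sample(paths: dict, k: int = 31, min_count=20,
                           canonical: bool = True) -> dict:
    """Count k-mers for many samples.

    ``min_count`` may be a single threshold or a ``{sample_id: threshold}``
    map — deeply sequenced samples accumulate sequencing-error k-mers above
    any fixed cutoff, so their threshold is often raised (e.g. 20 to 50).
    """
    out = {}
    for sample_id, path in paths.items():
        mc = min_count[sample_id] if isinstance(min_count, dict) else min_count
        out[sample_id] = count_kmers(path, k=k, min_count=mc, canonical=canonical)
    return out


@dataclass
class KmerMatrix:
    """Sparse sample x k-mer matrix with its vocabulary."""

    sample_ids: list
    vocabulary: list
    values: sparse.csr_matrix
    k: int
    canonical: bool

    def __post_init__(self):
        if self.values.shape != (len(self.sample_ids), len(self.vocabulary)):
            raise ValueError("matrix shape must match ids and vocabulary")
        for kmer in self.vocabulary:
            if len(kmer) != self.k or not set(kmer) <= _VALID:
                raise ValueError(f"invalid k-mer in vocabulary: {kmer!r}")

    def to_table(self, labels: dict | None = None) -> LabeledAbundanceTable:
        """Densify into the ensemble's table container (k-mers as 'taxa')."""
        return LabeledAbundanceTable(
            sample_ids=list(self.sample_ids),
            taxon_ids=list(self.vocabulary),
            lineages=list(self.vocabulary),
            values=self.values.toarray(),
            mode="relative",
            labels=None if labels is None else [labels[s] for s in self.sample_ids],
        )

    def write(self, prefix) -> None:
        """Serialize as a sparse triplet TSV plus a vocabulary file."""
        prefix = Path(prefix)
        coo = self.values.tocoo()
        with open(prefix.with_suffix(".triplets.tsv"), "w") as fh:
            fh.write(f"# k={self.k}\tcanonical={int(self.canonical)}\n")
            fh.write("sample\tkmer_index\tvalue\n")
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{self.sample_ids[i]}\t{j}\t{v:.10g}\n")
        with open(prefix.with_suffix(".vocab.txt"), "w") as fh:
            fh.write("\n".join(self.vocabulary) + "\n")


def build_kmer_matrix(count_maps: dict, min_prevalence: float = 0.10) -> KmerMatrix:
    """Assemble, prevalence-filter and row-normalise the k-mer matrix.

    The vocabulary is the union over samples; k-mers present (count > 0) in
    fewer than ``min_prevalence`` of the samples are dropped (the threshold
    is inclusive: exactly 10% of samples keeps the k-mer).  Surviving counts
    are divided by each sample's surviving total, so rows sum to 1.  Samples
    whose surviving vector is empty are dropped with a warning.
    """
    if not count_maps:
        raise ValueError("need at least one sample")
    sample_ids = list(count_maps)
    n = len(sample_ids)
    lengths = {len(km) for counts in count_maps.values() for km in counts}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent k across samples: {sorted(lengths)}")
    k = lengths.pop() if lengths else 0

    prevalence: dict = {}
    for counts in count_maps.values():
        for kmer in counts:
            prevalence[kmer] = prevalence.get(kmer, 0) + 1
    vocab = sorted(km for km, p in prevalence.items() if p / n >= min_prevalence)
    if not vocab:
        raise EmptyResultError("no k-mer survives the prevalence filter")
    col = {km: j for j, km in enumerate(vocab)}

    rows, cols, data, kept = [], [], [], []
    for i, sid in enumerate(sample_ids):
        entries = [(col[km], c) for km, c in count_maps[sid].items() if km in col]
        total = sum(c for _, c in entries)
        if total == 0:
            logger.warning("sample %s has no surviving k-mers; dropped", sid)
            continue
        kept.append(sid)
        r = len(kept) - 1
        for j, c in entries:
            rows.append(r)
            cols.append(j)
            data.append(c / total)
    if not kept:
        raise EmptyResultError("every sample lost all k-mers")
    mat = sparse.csr_matrix((data, (rows, cols)), shape=(len(kept), len(vocab)))
    canonical = all(km <= reverse_complement(km) for km in vocab)
    return KmerMatrix(kept, vocab, mat, k=k, canonical=canonical)
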