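"""Synthetic multi-city microbiome data with known ground truth.

Emulates the statistical structure of a city-labelled shotgun-metagenomics
abundance dataset: a modest number of cities with unequal sample counts,
thousands-to-hundreds of taxa with hierarchical lineage strings,
city-specific "signature" taxa shifted on the log scale, heavy within-city
overdispersion so the city clouds overlap, and optionally a confusable city
pair that shares most of its signatures (mimicking geographically or
microbially close city pairs).  Counts are drawn from a
Dirichlet-multinomial: city profile pi_c = softmax(baseline + effects), a
per-sample composition ~ Dirichlet(concentration * pi_c), then counts ~
Multinomial(library size).

A companion generator emits tiny per-sample FASTA read sets in which
city-specific marker subsequences are embedded at a stated rate, so the
taxonomy-free k-mer path can be exercised end to end at desk scale.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so every artefact is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .abundance import LabeledAbundanceTable
from .errors import ConfigurationError

_RANK_PREFIXES = ["d", "p", "c", "o", "f", "g", "s"]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the package's reference scenario: four cities with a
    40/20/20/8 imbalance (the 8-sample city plays the minority role), 300
    taxa, ten signature taxa per city at a log-fold effect of 2, and one
    confusable pair sharing 60% of its signatures.
    """

    n_cities: int = 4
    samples_per_city: tuple = (40, 20, 20, 8)
    n_taxa: int = 300
    n_signature_taxa_per_city: int = 10
    signature_log_fold: float = 2.0
    dirichlet_concentration: float = 100.0
    library_size_range: tuple = (5000, 20000)
    confusable_pairs: tuple = ((1, 2),)
    shared_signature_fraction: float = 0.6
    taxonomy_ranks: int = 7
    seed: int = 0

    def __post_init__(self):
        if self.n_cities < 1 or self.n_taxa < 1 or self.taxonomy_ranks < 1:
            raise ConfigurationError("counts must be >= 1")
        if len(self.samples_per_city) != self.n_cities:
            raise ConfigurationError(
                f"samples_per_city has {len(self.samples_per_city)} entries "
                f"for {self.n_cities} cities"
            )
        if any(n < 1 for n in self.samples_per_city):
            raise ConfigurationError("every city needs at least one sample")
        if self.n_signature_taxa_per_city < 1:
            raise ConfigurationError("need at least one signature taxon per city")
        if self.n_cities * self.n_signature_taxa_per_city > self.n_taxa:
            raise ConfigurationError("more signature taxa requested than taxa exist")
        lo, hi = self.library_size_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("library_size_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.shared_signature_fraction <= 1.0:
            raise ConfigurationError("shared_signature_fraction must be in [0, 1]")
        if self.dirichlet_concentration <= 0:
            raise ConfigurationError("dirichlet_concentration must be positive")
        for i, j in self.confusable_pairs:
            if not (0 <= i < self.n_cities and 0 <= j < self.n_cities) or i == j:
                raise ConfigurationError(f"invalid confusable pair ({i}, {j})")

    @property
    def city_names(self) -> list:
        return [f"city{c:02d}" for c in range(self.n_cities)]


@dataclass
class GroundTruth:
    """What the generator planted, for validating recovery downstream."""

    city_log_profiles: dict  # city -> per-taxon log-abundance vector
    signature_taxa: dict     # city -> {taxon index: log-fold effect}
    sample_labels: list      # city label per sample, generation order
    library_sizes: np.ndarray = field(default_factory=lambda: np.array([]))

    def all_signature_indices(self) -> set:
        return {i for sigs in self.signature_taxa.values() for i in sigs}

    def to_json(self, path) -> None:
        payload = {
            "city_log_profiles": {c: list(map(float, v)) for c, v in self.city_log_profiles.items()},
            "signature_taxa": {
                c: {str(i): float(e) for i, e in sigs.items()}
                for c, sigs in self.signature_taxa.items()
            },
            "sample_labels": list(self.sample_labels),
            "library_sizes": [int(x) for x in self.library_sizes],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _spawn(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _assign_signatures(config: SyntheticConfig, rng) -> dict:
    """Pick each city's signature taxon indices; confusable pairs overlap."""
    pool = rng.permutation(config.n_taxa)
    n_sig = config.n_signature_taxa_per_city
    sigs = {c: list(pool[c * n_sig:(c + 1) * n_sig]) for c in range(config.n_cities)}
    n_shared = int(round(config.shared_signature_fraction * n_sig))
    for i, j in config.confusable_pairs:
        # city j adopts the first n_shared signatures of city i
        sigs[j] = sigs[i][:n_shared] + sigs[j][n_shared:]
    return {c: [int(t) for t in idx] for c, idx in sigs.items()}


def _lineages(config: SyntheticConfig, rng) -> list:
    """Hierarchical lineage strings with consistent clade prefixes.

    Taxa are shuffled once, then chunked into nested blocks whose counts
    double per rank (powers of two keep the nesting exact); the final rank
    is a unique species name.
    """
    n, ranks = config.n_taxa, config.taxonomy_ranks
    order = rng.permutation(n)
    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(n)
    lineages = []
    for i in range(n):
        parts = []
        for r in range(ranks - 1):
            groups = min(2 ** (r + 1), n)
            gid = (pos[i] * groups) // n
            prefix = _RANK_PREFIXES[min(r, len(_RANK_PREFIXES) - 2)]
            parts.append(f"{prefix}__clade{r}_{gid}")
        parts.append(f"s__taxon{i:05d}")
        lineages.append("|".join(parts))
    return lineages


def generate_dataset(config: SyntheticConfig):
    """Draw one labelled count table plus its ground truth.

    Returns ``(LabeledAbundanceTable, GroundTruth)``.  Row sums of the count
    matrix equal the drawn library sizes exactly; identical configs (same
    seed) reproduce the table bit-identically.
    """
    rng_base, rng_sig, rng_tax, rng_lib, rng_draw = _spawn(config.seed, 5)
    baseline = rng_base.normal(0.0, 1.0, config.n_taxa)
    signatures = _assign_signatures(config, rng_sig)
    lineages = _lineages(config, rng_tax)

    profiles, sig_effects = {}, {}
    for c, city in enumerate(config.city_names):
        effects = np.zeros(config.n_taxa)
        effects[signatures[c]] = config.signature_log_fold
        profiles[city] = baseline + effects
        sig_effects[city] = {i: config.signature_log_fold for i in signatures[c]}

    n_total = int(sum(config.samples_per_city))
    lo, hi = config.library_size_range
    lib_sizes = rng_lib.integers(lo, hi + 1, size=n_total)

    counts = np.zeros((n_total, config.n_taxa), dtype=int)
    labels, sample_ids = [], []
    row = 0
    for c, city in enumerate(config.city_names):
        logp = profiles[city]
        pi = np.exp(logp - logp.max())
        pi /= pi.sum()
        alpha = config.dirichlet_concentration * pi
        for s in range(config.samples_per_city[c]):
            comp = rng_draw.dirichlet(alpha)
            counts[row] = rng_draw.multinomial(lib_sizes[row], comp)
            labels.append(city)
            sample_ids.append(f"{city}_s{s:03d}")
            row += 1

    table = LabeledAbundanceTable(
        sample_ids=sample_ids,
        taxon_ids=[f"s__taxon{i:05d}" for i in range(config.n_taxa)],
        lineages=lineages,
        values=counts,
        mode="counts",
        labels=labels,
    )
    truth = GroundTruth(
        city_log_profiles=profiles,
        signature_taxa=sig_effects,
        sample_labels=labels,
        library_sizes=lib_sizes,
    )
    return table, truth


@dataclass
class ReadFixtures:
    """Per-sample FASTA paths, their city labels and the planted markers."""

    sample_paths: dict   # sample_id -> Path
    labels: dict         # sample_id -> city
    city_markers: dict   # city -> list of marker sequences


def generate_read_fixtures(
    config: SyntheticConfig,
    reads_per_sample: int,
    read_length: int,
    out_dir,
    marker_rate: float = 0.3,
    markers_per_city: int = 1,
    marker_length: int = 31,
    min_k: int = 31,
) -> ReadFixtures:
    """Write tiny per-sample FASTA files with city markers embedded.

    Each read is uniform random ACGT; with probability ``marker_rate`` one of
    the city's marker sequences is overwritten at a random offset, so k-mer
    counts of the markers carry the city label.  ``read_length`` must be at
    least ``min_k`` (the k intended downstream) or the k-mer path would see
    no signal at all.
    """
    if read_length < min_k:
        raise ConfigurationError(
            f"read_length {read_length} is shorter than the downstream k ({min_k})"
        )
    if marker_length > read_length:
        raise ConfigurationError("marker_length cannot exceed read_length")
    if not 0.0 <= marker_rate <= 1.0:
        raise ConfigurationError("marker_rate must be in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng_marker, rng_reads = _spawn(config.seed + 1, 2)
    bases = np.array(list("ACGT"))

    markers = {
        city: ["".join(rng_marker.choice(bases, marker_length)) for _ in range(markers_per_city)]
        for city in config.city_names
    }

    paths, labels = {}, {}
    for c, city in enumerate(config.city_names):
        for s in range(config.samples_per_city[c]):
            sample_id = f"{city}_s{s:03d}"
            path = out_dir / f"{sample_id}.fasta"
            with open(path, "w") as fh:
                for r in range(reads_per_sample):
                    read = rng_reads.choice(bases, read_length)
                    if rng_reads.random() < marker_rate:
                        marker = markers[city][rng_reads.integers(len(markers[city]))]
                        off = rng_reads.integers(0, read_length - marker_length + 1)
                        read[off:off + marker_length] = list(marker)
                    fh.write(f">{sample_id}_r{r}\n{''.join(read)}\n")
            paths[sample_id] = path
            labels[sample_id] = city
    return ReadFixtures(sample_paths=paths, labels=labels, city_markers=markers)
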