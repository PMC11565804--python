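"""Bind-n-seq k-mer enrichment, G4 motif matching and FOREST normalization.

The bind-n-seq readout compares a protein-bound read pool against its input
pool.  For a k-mer, the enrichment statistic R is the frequency of that
k-mer among all k-mer instances of the bound pool divided by its frequency
in the input pool; R = 1 means no preference.  Strong G-quadruplex-forming
sequences are identified with the run/loop pattern (G{3-6} N{0-7}){4}: four
guanine runs of 3-6 nt separated by three loops of 0-7 nt.  Matching is by
existence of ANY valid run/loop decomposition (a greedy regex over-commits
to long G runs and misses valid splits), implemented as a backtracking scan.

Reads are RNA; DNA-letter input (T, mixed case) is normalized to uppercase
U on ingestion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "RNA_ALPHABET",
    "ReadPool",
    "KmerTable",
    "PatternSpec",
    "read_pool_fasta",
    "read_pool_fastq",
    "write_pool_fasta",
    "count_kmers",
    "kmer_enrichment",
    "match_strong_g4",
    "has_strong_g4",
    "classify_pool",
    "pattern_enrichment",
    "forest_normalize",
]

RNA_ALPHABET = ("A", "C", "G", "U")


def normalize_rna(seq: str) -> str:
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - set(RNA_ALPHABET)
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return s


@dataclass
class ReadPool:
    """A pool of RNA reads with optional constant adapters."""

    reads: list[str]
    label: str = ""
    adapter_5p: str = ""
    adapter_3p: str = ""

    def __post_init__(self) -> None:
        self.reads = [normalize_rna(r) for r in self.reads]
        if any(not r for r in self.reads):
            raise ValueError("reads must be non-empty")
        self.adapter_5p = normalize_rna(self.adapter_5p) if self.adapter_5p else ""
        self.adapter_3p = normalize_rna(self.adapter_3p) if self.adapter_3p else ""

    def __len__(self) -> int:
        return len(self.reads)

    def effective_reads(self, include_adapters: bool) -> list[str]:
        if not include_adapters or not (self.adapter_5p or self.adapter_3p):
            return self.reads
        return [self.adapter_5p + r + self.adapter_3p for r in self.reads]


@dataclass
class KmerTable:
    """k-mer counts and instance frequencies of one pool."""

    k: int
    counts: dict[str, int]
    total: int

    @property
    def frequencies(self) -> dict[str, float]:
        return {kmer: c / self.total for kmer, c in self.counts.items()}


@dataclass(frozen=True)
class PatternSpec:
    """Parametrized G-run/loop motif, default (G{3-6} N{0-7}){4}.

    ``min_g_for_control`` is the guanine count (in the randomized region) at
    or above which a non-matching read is labelled a non-G4 control; the
    threshold uses >= semantics and is configurable.
    """

    g_run_min: int = 3
    g_run_max: int = 6
    loop_max: int = 7
    n_runs: int = 4
    min_g_for_control: int = 8

    def __post_init__(self) -> None:
        if not (1 <= self.g_run_min <= self.g_run_max):
            raise ValueError("need 1 <= g_run_min <= g_run_max")
        if self.loop_max < 0 or self.n_runs < 2:
            raise ValueError("loop_max >= 0 and n_runs >= 2 required")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_pool_fasta(path: str | Path, label: str = "",
                    adapter_5p: str = "", adapter_3p: str = "") -> ReadPool:
    reads = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    return ReadPool(reads, label or Path(path).stem, adapter_5p, adapter_3p)


def read_pool_fastq(path: str | Path, label: str = "",
                    adapter_5p: str = "", adapter_3p: str = "") -> ReadPool:
    reads = [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
    return ReadPool(reads, label or Path(path).stem, adapter_5p, adapter_3p)


def write_pool_fasta(pool: ReadPool, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, read in enumerate(pool.reads):
            fh.write(f">{pool.label or 'read'}_{i}\n{read}\n")


# ---------------------------------------------------------------------------
# k-mer statistics
# ---------------------------------------------------------------------------

def count_kmers(pool: ReadPool, k: int, include_adapters: bool = False) -> KmerTable:
    """Sliding-window k-mer instance counts over every read of the pool."""
    seqs = pool.effective_reads(include_adapters)
    if k > max(len(s) for s in seqs):
        raise ValueError(f"k={k} exceeds every read length")
    counts: dict[str, int] = {}
    total = 0
    for s in seqs:
        for i in range(len(s) - k + 1):
            counts[s[i:i + k]] = counts.get(s[i:i + k], 0) + 1
            total += 1
    return KmerTable(k, counts, total)


def kmer_enrichment(
    bound: ReadPool,
    input_pool: ReadPool,
    k: int,
    include_adapters: bool = False,
    pseudocount: bool = False,
) -> pd.DataFrame:
    """Enrichment table R = freq_bound / freq_input per k-mer, R descending.

    k-mers absent from the input pool are excluded unless ``pseudocount``
    adds one count per k-mer per pool.  Columns:
    ``kmer, R, count_bound, count_input``.
    """
    tb = count_kmers(bound, k, include_adapters)
    ti = count_kmers(input_pool, k, include_adapters)
    rows = []
    add = 1 if pseudocount else 0
    universe = set(tb.counts) | set(ti.counts) if pseudocount else set(ti.counts)
    tot_b = tb.total + add * len(universe)
    tot_i = ti.total + add * len(universe)
    for kmer in universe:
        cb = tb.counts.get(kmer, 0) + add
        ci = ti.counts.get(kmer, 0) + add
        if ci == 0:
            continue
        rows.append((kmer, (cb / tot_b) / (ci / tot_i), cb - add, ci - add))
    df = pd.DataFrame(rows, columns=["kmer", "R", "count_bound", "count_input"])
    return df.sort_values(["R", "kmer"], ascending=[False, True], ignore_index=True)


# ---------------------------------------------------------------------------
# G4 pattern matching
# ---------------------------------------------------------------------------

def match_strong_g4(seq: str, spec: PatternSpec | None = None) -> list[tuple[int, int]]:
    """Spans ``[start, end)`` of the strong-G4 run/loop pattern in ``seq``.

    A span is reported when some decomposition into ``n_runs`` G-runs (each
    ``g_run_min..g_run_max`` long) separated by loops of ``0..loop_max``
    arbitrary nucleotides starts at ``start`` and ends at ``end``.  All
    distinct spans are returned, sorted.
    """
    spec = spec or PatternSpec()
    s = normalize_rna(seq)
    n = len(s)

    # g_run_len[i] = length of the maximal G run starting at i
    run_len = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        run_len[i] = run_len[i + 1] + 1 if s[i] == "G" else 0

    spans: set[tuple[int, int]] = set()
    visited: set[tuple[int, int, int]] = set()

    def extend(pos: int, runs_left: int, start: int) -> None:
        """Try to place a G-run at exactly ``pos`` and recurse over loops."""
        if (pos, runs_left, start) in visited:
            return
        visited.add((pos, runs_left, start))
        max_run = min(run_len[pos], spec.g_run_max)
        if max_run < spec.g_run_min:
            return
        for rl in range(spec.g_run_min, max_run + 1):
            end_run = pos + rl
            if runs_left == 1:
                spans.add((start, end_run))
                continue
            for loop in range(0, spec.loop_max + 1):
                nxt = end_run + loop
                if nxt >= n:
                    break
                extend(nxt, runs_left - 1, start)

    for i in range(n):
        if run_len[i] >= spec.g_run_min:
            extend(i, spec.n_runs, i)
    return sorted(spans)


def has_strong_g4(seq: str, spec: PatternSpec | None = None) -> bool:
    """True when any strong-G4 decomposition exists in ``seq``."""
    return bool(match_strong_g4(seq, spec))


def classify_pool(
    pool: ReadPool,
    spec: PatternSpec | None = None,
    include_adapters: bool = True,
) -> tuple[list[str], dict[str, float]]:
    """Per-read class labels and summary fractions.

    ``strong_g4``: the run/loop pattern matches (searched, by default, on the
    randomized region plus adapters, which are part of the RNA presented to
    the protein).  ``non_g4_control``: no match and the randomized region
    holds at least ``min_g_for_control`` guanines.  Everything else:
    ``other``.  Fractions sum to 1.
    """
    spec = spec or PatternSpec()
    search_seqs = pool.effective_reads(include_adapters)
    labels = []
    for read, search in zip(pool.reads, search_seqs):
        if has_strong_g4(search, spec):
            labels.append("strong_g4")
        elif read.count("G") >= spec.min_g_for_control:
            labels.append("non_g4_control")
        else:
            labels.append("other")
    n = len(labels)
    fractions = {c: labels.count(c) / n for c in ("strong_g4", "non_g4_control", "other")}
    return labels, fractions


def pattern_enrichment(
    bound: ReadPool,
    input_pool: ReadPool,
    spec: PatternSpec | None = None,
    class_label: str = "strong_g4",
    include_adapters: bool = True,
) -> float | None:
    """Read-level class enrichment: bound-pool fraction / input-pool fraction.

    Returns ``None`` (with a warning) when the class is absent from the
    input pool, where the ratio is undefined.
    """
    _, fb = classify_pool(bound, spec, include_adapters)
    _, fi = classify_pool(input_pool, spec, include_adapters)
    if fi[class_label] == 0:
        warnings.warn(f"class {class_label!r} absent from input pool; "
                      "enrichment undefined")
        return None
    return fb[class_label] / fi[class_label]


# ---------------------------------------------------------------------------
# FOREST normalization
# ---------------------------------------------------------------------------

def forest_normalize(
    signal: Mapping[str, float],
    control: Mapping[str, float],
    barcode_map: Mapping[str, str],
) -> dict[str, float]:
    """Control-subtracted, barcode-averaged probe intensities per structure.

    Net intensity = signal - control per probe (negatives retained), then the
    mean over all barcoded probes sharing a structure id.  A probe missing
    from the control (or the barcode map) is an error naming the probe.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for probe, value in signal.items():
        if probe not in control:
            raise KeyError(f"probe {probe!r} missing from control intensities")
        if probe not in barcode_map:
            raise KeyError(f"probe {probe!r} missing from barcode map")
        sid = barcode_map[probe]
        sums[sid] = sums.get(sid, 0.0) + (value - control[probe])
        counts[sid] = counts.get(sid, 0) + 1
    return {sid: sums[sid] / counts[sid] for sid in sums}
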