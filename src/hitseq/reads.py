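"""Raw reads -> UMI-collapsed per-variant counts per protein concentration.

Reads are parsed by fixed coordinates (2-nt UMI, 3-nt index barcode, 24-nt
constant region, 7-mer, 3' constant), accepted when the constant region is
within Hamming distance 1 of the expected sequence (no gaps), demultiplexed by
exact index match, and counted per 7-mer variant.  Both raw read counts and
UMI-collapsed counts (distinct (UMI, 7-mer) pairs) are kept: with only
4^2 = 16 possible 2-nt UMIs, collapsed counts saturate at 16 per (library,
variant) cell, so deep libraries should be quantified with raw counts and a
PCR-duplication-free protocol, while collapsed counts correct moderate
overamplification.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .sequences import BASE_CODE, all_kmers, dna_to_rna
from .simulate import ConstructLayout, ReadSet

REJECT_TOO_SHORT = "too_short"
REJECT_CONSTANT = "constant_mismatch"
REJECT_INVALID = "invalid_base"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ParsedRead:
    umi: str
    index: str
    kmer: str  # RNA alphabet (ACGU)
    constant_mismatches: int


@dataclass(frozen=True)
class Rejection:
    reason: str


def parse_construct(
    read: str, layout: ConstructLayout | None = None, max_mismatch: int = 1
) -> Union[ParsedRead, Rejection]:
    """Split one read into UMI / index / 7-mer, or reject it.

    The constant region (read positions 6-29, 1-based) is compared to the
    expected sequence by Hamming distance with no gaps; reads farther than
    ``max_mismatch`` are rejected.  The 7-mer is taken verbatim — errors inside
    the randomized window are indistinguishable from real variants.
    """
    layout = layout or ConstructLayout()
    if len(read) < layout.min_parse_len:
        return Rejection(REJECT_TOO_SHORT)
    constant = read[layout.constant_start : layout.kmer_start]
    mismatches = sum(a != b for a, b in zip(constant, layout.constant5))
    if mismatches > max_mismatch:
        return Rejection(REJECT_CONSTANT)
    variable = read[: layout.constant_start] + read[layout.kmer_start : layout.kmer_end]
    if any(ch not in "ACGT" for ch in variable):
        return Rejection(REJECT_INVALID)
    return ParsedRead(
        umi=read[: layout.umi_len],
        index=read[layout.umi_len : layout.constant_start],
        kmer=dna_to_rna(read[layout.kmer_start : layout.kmer_end]),
        constant_mismatches=mismatches,
    )


def demultiplex(
    parsed: Iterable[ParsedRead], index_table: Mapping[str, str]
) -> dict[str, list[ParsedRead]]:
    """Group parsed reads by library via exact 3-nt index match.

    ``index_table`` maps index barcode -> library label.  Reads whose barcode
    is not in the table land in the ``"unassigned"`` group.
    """
    labels = list(index_table.values())
    if len(set(index_table.keys())) != len(index_table):
        raise ValueError("index table keys must be unique")
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate library labels in index table: {sorted(labels)}")
    groups: dict[str, list[ParsedRead]] = {label: [] for label in labels}
    groups[UNASSIGNED] = []
    for pr in parsed:
        groups[index_table.get(pr.index, UNASSIGNED)].append(pr)
    return groups


@dataclass
class CountTable:
    """Per-variant read counts per library, raw and UMI-collapsed.

    ``counts`` are raw accepted-read counts, ``umi_counts`` collapse identical
    (UMI, 7-mer) pairs within a library.  Both are dense over all 16,384
    variants; ``control_label`` names the no-protein library.
    """

    counts: pd.DataFrame
    umi_counts: pd.DataFrame
    control_label: str
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.control_label not in self.counts.columns:
            raise ValueError(
                f"control library {self.control_label!r} missing from count table"
            )
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def labels(self) -> list[str]:
        return list(self.counts.columns)

    def table(self, which: str = "raw") -> pd.DataFrame:
        if which == "raw":
            return self.counts
        if which == "umi":
            return self.umi_counts
        raise ValueError(f"unknown count table {which!r}; use 'raw' or 'umi'")

    def to_tsv(self, path, which: str = "raw") -> None:
        out = self.table(which).copy()
        out.insert(0, "variant", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, control_label: str) -> "CountTable":
        df = pd.read_csv(path, sep="\t").set_index("variant")
        return cls(counts=df, umi_counts=df.copy(), control_label=control_label)


def _dense_index() -> pd.Index:
    return pd.Index(all_kmers(7), name="variant")


def dedup_and_count(
    groups: Mapping[str, list[ParsedRead]], control_label: str | None = None
) -> CountTable:
    """Collapse (UMI, 7-mer) duplicates within each library and count variants.

    The UMI-collapsed count of variant v is the number of distinct UMIs seen
    with v in that library; raw counts are reported alongside.
    """
    labels = [lb for lb in groups.keys() if lb != UNASSIGNED]
    index = _dense_index()
    raw = pd.DataFrame(0, index=index, columns=labels, dtype=np.int64)
    collapsed = pd.DataFrame(0, index=index, columns=labels, dtype=np.int64)
    n_umis = 0
    for label in labels:
        prs = groups[label]
        if not prs:
            continue
        raw_counts = pd.Series([pr.kmer for pr in prs]).value_counts()
        raw.loc[raw_counts.index, label] = raw_counts
        distinct = {(pr.umi, pr.kmer) for pr in prs}
        umi_counts = pd.Series([kmer for _, kmer in distinct]).value_counts()
        collapsed.loc[umi_counts.index, label] = umi_counts
        n_umis = max(n_umis, len({pr.umi for pr in prs}))
    table = CountTable(
        counts=raw,
        umi_counts=collapsed,
        control_label=control_label or labels[0],
        stats={"unassigned": len(groups.get(UNASSIGNED, []))},
    )
    _warn_umi_saturation(table)
    return table


def _warn_umi_saturation(table: CountTable, n_umis: int = 16) -> None:
    saturated = int((table.umi_counts.to_numpy() >= n_umis).sum())
    if saturated:
        warnings.warn(
            f"{saturated} (library, variant) cells reached the {n_umis}-UMI "
            "ceiling; UMI-collapsed counts are saturated there — use raw counts "
            "for deep libraries"
        )


def _read_fastq_matrix(path, read_len: int) -> np.ndarray:
    """Load FASTQ sequences into an ASCII matrix (shorter reads 0-padded)."""
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        seqs = [str(rec.seq) for rec in SeqIO.parse(fh, "fastq")]
    mat = np.zeros((len(seqs), read_len), dtype=np.uint8)
    for i, s in enumerate(seqs):
        b = s.encode()[:read_len]
        mat[i, : len(b)] = np.frombuffer(b, dtype=np.uint8)
    return mat


def count_reads(
    source: Union[ReadSet, str],
    index_table: Mapping[str, str],
    layout: ConstructLayout | None = None,
    max_mismatch: int = 1,
    control_label: str | None = None,
) -> CountTable:
    """Vectorised parse + demultiplex + count for a ReadSet or FASTQ path.

    Equivalent to parse_construct / demultiplex / dedup_and_count applied
    read by read, but runs on the whole read matrix at once.
    """
    layout = layout or ConstructLayout()
    if isinstance(source, ReadSet):
        mat = source.seqs
    else:
        mat = _read_fastq_matrix(source, layout.read_len)
    labels = list(index_table.values())
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate library labels in index table: {sorted(labels)}")
    index = _dense_index()
    raw = pd.DataFrame(0, index=index, columns=labels, dtype=np.int64)
    collapsed = pd.DataFrame(0, index=index, columns=labels, dtype=np.int64)
    stats = {
        "total": int(len(mat)),
        "accepted": 0,
        REJECT_TOO_SHORT: 0,
        REJECT_CONSTANT: 0,
        REJECT_INVALID: 0,
        UNASSIGNED: 0,
    }
    if len(mat):
        # reads shorter than the parseable window carry trailing NUL padding
        long_enough = (mat[:, : layout.min_parse_len] != 0).all(axis=1)
        stats[REJECT_TOO_SHORT] = int((~long_enough).sum())
        const_expect = np.frombuffer(layout.constant5.encode(), dtype=np.uint8)
        mism = (
            mat[:, layout.constant_start : layout.kmer_start] != const_expect
        ).sum(axis=1)
        ok = long_enough & (mism <= max_mismatch)
        stats[REJECT_CONSTANT] = int((long_enough & ~(mism <= max_mismatch)).sum())

        umi_codes = BASE_CODE[mat[:, : layout.umi_len]]
        idx_codes = BASE_CODE[mat[:, layout.umi_len : layout.constant_start]]
        kmer_codes = BASE_CODE[mat[:, layout.kmer_start : layout.kmer_end]]
        valid = ok & (umi_codes != 255).all(axis=1) & (kmer_codes != 255).all(axis=1)
        stats[REJECT_INVALID] = int((ok & ~valid).sum())

        pow4 = lambda n: 4 ** np.arange(n - 1, -1, -1, dtype=np.int64)  # noqa: E731
        umi_id = umi_codes[valid].astype(np.int64) @ pow4(layout.umi_len)
        kmer_id = kmer_codes[valid].astype(np.int64) @ pow4(layout.random_len)
        idx_ok = (idx_codes != 255).all(axis=1)
        idx_id = np.where(
            idx_ok, idx_codes.astype(np.int64) @ pow4(layout.index_len), -1
        )[valid]

        lib_of_index = np.full(4**layout.index_len, -1, dtype=np.int64)
        for barcode, label in index_table.items():
            codes = BASE_CODE[np.frombuffer(barcode.encode(), dtype=np.uint8)]
            if (codes == 255).any() or len(barcode) != layout.index_len:
                raise ValueError(f"invalid index barcode {barcode!r}")
            lib_of_index[codes.astype(np.int64) @ pow4(layout.index_len)] = labels.index(
                label
            )
        lib_id = np.where(idx_id >= 0, lib_of_index[np.maximum(idx_id, 0)], -1)
        stats[UNASSIGNED] = int((lib_id < 0).sum())
        assigned = lib_id >= 0
        stats["accepted"] = int(assigned.sum())

        lib_a, umi_a, kmer_a = lib_id[assigned], umi_id[assigned], kmer_id[assigned]
        n_kmers = 4**layout.random_len
        raw_flat = np.bincount(lib_a * n_kmers + kmer_a, minlength=len(labels) * n_kmers)
        raw.iloc[:, :] = raw_flat.reshape(len(labels), n_kmers).T
        n_umis = 4**layout.umi_len
        pair_key = (lib_a * n_umis + umi_a) * n_kmers + kmer_a
        uniq = np.unique(pair_key)
        uk_kmer = uniq % n_kmers
        uk_lib = uniq // n_kmers // n_umis
        coll_flat = np.bincount(
            uk_lib * n_kmers + uk_kmer, minlength=len(labels) * n_kmers
        )
        collapsed.iloc[:, :] = coll_flat.reshape(len(labels), n_kmers).T

    table = CountTable(
        counts=raw,
        umi_counts=collapsed,
        control_label=control_label or labels[0],
        stats=stats,
    )
    _warn_umi_saturation(table)
    return table


def normalize_counts(
    table: CountTable,
    pseudocount: float = 0.5,
    which: str = "raw",
) -> pd.DataFrame:
    """Depletion/enrichment of each variant relative to the no-protein control.

    normalized(v, E) = frequency of v in library E divided by its frequency in
    the control, with ``pseudocount`` added to every cell first.  Values < 1
    mean depletion from the free pool (binding), > 1 enrichment.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    counts = table.table(which).astype(float) + pseudocount
    freqs = counts / counts.sum(axis=0)
    control = freqs[table.control_label]
    if control.sum() <= 0:
        raise ValueError("control library is empty")
    return freqs.div(control, axis=0)
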