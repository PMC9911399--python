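"""Synthetic HiTS-Eq experiment generator.

HiTS-Eq (High Throughput Sequencing Equilibrium binding) measures relative
binding affinities by sequencing the *unbound* fraction of a randomized RNA
pool equilibrated with increasing protein concentrations: well-bound variants
are depleted from the free pool, poorly-bound ones are not.  This module
provides (i) ground-truth affinity landscapes over all 16,384 7-mer variants,
(ii) exact equilibrium partitioning of the pool, and (iii) sequencing-read
simulation (UMIs, index barcodes, PCR duplication, substitution errors) so the
whole downstream pipeline can be exercised and validated without any external
data.

Model assumptions
-----------------
Binding is pseudo-first-order: total protein (uM range) vastly exceeds the
RNA pool (1 nM spread over 16,384 species), so free protein ~ total protein
and the free fraction of variant v at protein concentration E is
``kd(v) / (kd(v) + E)``.  Adapter-masking oligos are assumed fully effective,
i.e. no secondary-structure bias is simulated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequences import (
    BASE_CODE,
    CODE_TO_DNA,
    all_kmers,
    encode_kmers,
    rna_to_dna,
    validate_sequence,
)

# Randomized construct: 24-nt 5' constant / 7 random nt / 22-nt 3' constant.
CONSTANT5_RNA = "GGGAGACCGGAAUUCAGAUUGUCC"
CONSTANT3_RNA = "UUAAAUCCCGUCGUAGCCACCA"

#: 3-nt library index barcodes, one per sequencing library.
INDEX_SEQUENCES = ("ATC", "GAT", "CGA", "TCC", "CAC", "TGT", "ACT", "GTA")

N_VARIANTS = 4**7  # 16,384

#: reference (cognate) variant used to normalise relative affinities
REFERENCE_VARIANT = "UGCAUGU"

#: default protein series: no-protein control plus 7 log-spaced points up to
#: 19,740 nM (the highest concentration used in the experiment this emulates)
DEFAULT_CONCS = (0.0,) + tuple(
    float(x) for x in np.geomspace(2.0, 19740.0, 7)
)


@dataclass(frozen=True)
class ConstructLayout:
    """Read anatomy: UMI + index + 5' constant + 7-mer + 3' constant prefix.

    Positions (0-based) in a read: [0,2) UMI, [2,5) index, [5,29) constant
    region, [29,36) randomized 7-mer, [36,read_len) prefix of the 3' constant.
    """

    umi_len: int = 2
    index_len: int = 3
    constant5: str = rna_to_dna(CONSTANT5_RNA)
    random_len: int = 7
    constant3: str = rna_to_dna(CONSTANT3_RNA)
    read_len: int = 50

    @property
    def constant_start(self) -> int:
        return self.umi_len + self.index_len

    @property
    def kmer_start(self) -> int:
        return self.constant_start + len(self.constant5)

    @property
    def kmer_end(self) -> int:
        return self.kmer_start + self.random_len

    @property
    def min_parse_len(self) -> int:
        return self.kmer_end

    def template(self) -> np.ndarray:
        """ASCII template row with constant parts filled, variable parts 'N'."""
        row = np.full(self.read_len, ord("N"), dtype=np.uint8)
        c5 = np.frombuffer(self.constant5.encode(), dtype=np.uint8)
        row[self.constant_start : self.kmer_start] = c5
        tail = self.constant3.encode()[: self.read_len - self.kmer_end]
        row[self.kmer_end : self.kmer_end + len(tail)] = np.frombuffer(
            tail, dtype=np.uint8
        )
        return row


@dataclass(frozen=True)
class LandscapeParams:
    """Parameters of the bimodal ground-truth landscape.

    Dissociation constants are drawn from a two-component log-normal: variants
    containing a cognate motif (default 5'-GCAUG) come from a tight
    high-affinity mode, all others from a broad low-affinity mode.  Defaults
    put the cognate mode near the low-nanomolar K_1/2 of the consensus site
    and the background mode in the 10 uM range, well separated on the ln-Kd
    scale, which reproduces the bimodal affinity distribution the assay sees
    for a highly specific RNA-binding domain.
    """

    cognate_motifs: tuple[str, ...] = ("GCAUG",)
    cognate_log_kd_mean: float = math.log(3.0)  # ln nM
    cognate_log_kd_sd: float = 0.7
    background_log_kd_mean: float = math.log(8000.0)  # ln nM
    background_log_kd_sd: float = 1.0

    def __post_init__(self) -> None:
        for motif in self.cognate_motifs:
            validate_sequence(motif, what="cognate motif")
        if self.cognate_log_kd_sd < 0 or self.background_log_kd_sd < 0:
            raise ValueError("log-Kd spreads must be nonnegative")


@dataclass
class AffinityLandscape:
    """Ground-truth per-variant dissociation constants (nM) for simulation."""

    variants: np.ndarray  # 16,384 unique 7-mers (RNA alphabet)
    kd: np.ndarray  # nM, > 0
    mode_label: np.ndarray  # "cognate-mode" / "non-cognate-mode"
    params: object | None = None

    def __post_init__(self) -> None:
        self.variants = np.asarray(self.variants, dtype="U7")
        self.kd = np.asarray(self.kd, dtype=float)
        self.mode_label = np.asarray(self.mode_label, dtype="U20")
        if len(self.variants) != N_VARIANTS:
            raise ValueError(
                f"landscape must cover all {N_VARIANTS} 7-mers, got {len(self.variants)}"
            )
        if len(np.unique(self.variants)) != len(self.variants):
            raise ValueError("landscape variants must be unique")
        if not (self.kd > 0).all():
            raise ValueError("all dissociation constants must be positive")

    @property
    def kd_series(self) -> pd.Series:
        return pd.Series(self.kd, index=self.variants, name="kd_nM")

    def kd_of(self, variant: str) -> float:
        pos = np.flatnonzero(self.variants == variant)
        if len(pos) == 0:
            raise KeyError(variant)
        return float(self.kd[pos[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variant": self.variants, "kd_nM": self.kd, "mode": self.mode_label}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AffinityLandscape":
        df = pd.read_csv(path, sep="\t")
        return cls(
            variants=df["variant"].to_numpy(),
            kd=df["kd_nM"].to_numpy(),
            mode_label=df["mode"].to_numpy(),
        )


def _cognate_mask(variants: np.ndarray, motifs: tuple[str, ...]) -> np.ndarray:
    mask = np.zeros(len(variants), dtype=bool)
    for motif in motifs:
        mask |= np.char.find(variants.astype("U"), motif) >= 0
    return mask


def make_landscape(
    params: LandscapeParams | None = None, seed: int = 0
) -> AffinityLandscape:
    """Draw a bimodal ground-truth landscape over all 16,384 7-mers.

    Deterministic given ``seed``.  Every variant containing a cognate motif is
    assigned to the high-affinity mode.
    """
    params = params or LandscapeParams()
    rng = np.random.default_rng(seed)
    variants = np.array(all_kmers(7), dtype="U7")
    cognate = _cognate_mask(variants, params.cognate_motifs)
    log_kd = rng.normal(
        params.background_log_kd_mean, params.background_log_kd_sd, size=len(variants)
    )
    log_kd[cognate] = rng.normal(
        params.cognate_log_kd_mean, params.cognate_log_kd_sd, size=int(cognate.sum())
    )
    mode = np.where(cognate, "cognate-mode", "non-cognate-mode")
    return AffinityLandscape(
        variants=variants, kd=np.exp(log_kd), mode_label=mode, params=params
    )


def make_additive_landscape(
    coefficients: pd.DataFrame,
    baseline: str = REFERENCE_VARIANT,
    log_kd0: float = math.log(1.6),
    couplings: dict[tuple[int, int, str, str], float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AffinityLandscape:
    """Landscape whose ln(Kd) is additive over positions (plus pair couplings).

    ``coefficients`` is a (position x nucleotide) table of ln-Kd increments
    (rows 0..6, columns A/C/G/U); the baseline variant's nucleotides should
    carry coefficient 0 so that its Kd is ``exp(log_kd0)``.  ``couplings`` maps
    (i, j, base_i, base_j) with i < j to an extra ln-Kd increment applied when
    both bases are present.  Used for model-recovery tests where the true
    regression coefficients are known exactly.
    """
    validate_sequence(baseline, what="baseline")
    variants = np.array(all_kmers(7), dtype="U7")
    chars = variants.view(np.uint32).reshape(len(variants), 7).astype(np.uint8)
    log_kd = np.full(len(variants), float(log_kd0))
    coef = coefficients.astype(float)
    for i in range(7):
        lut = np.zeros(256)
        for b in "ACGU":
            lut[ord(b)] = coef.loc[i, b]
        log_kd += lut[chars[:, i]]
    if couplings:
        for (i, j, bi, bj), value in couplings.items():
            if not (0 <= i < j < 7):
                raise ValueError(f"invalid coupling positions ({i}, {j})")
            mask = (chars[:, i] == ord(bi)) & (chars[:, j] == ord(bj))
            log_kd[mask] += value
    if noise_sd > 0:
        log_kd += np.random.default_rng(seed).normal(0.0, noise_sd, len(variants))
    cognate = _cognate_mask(variants, ("GCAUG",))
    mode = np.where(cognate, "cognate-mode", "non-cognate-mode")
    return AffinityLandscape(variants=variants, kd=np.exp(log_kd), mode_label=mode)


@dataclass(frozen=True)
class SimulationConfig:
    """Experiment-level knobs of the simulated HiTS-Eq run.

    protein_concs: nM, ascending, first element 0 (the no-protein control).
    total_rna: total pool concentration in nM (1 nM in the emulated assay).
    depth: source molecules sampled per library before PCR duplication.
    pcr_duplication: mean reads per molecule (geometric duplication, >= 1).
    error_rate: per-base substitution probability.
    """

    protein_concs: tuple[float, ...] = DEFAULT_CONCS
    total_rna: float = 1.0
    depth: int = 1_000_000
    pcr_duplication: float = 1.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        concs = tuple(float(c) for c in self.protein_concs)
        if len(concs) == 0 or concs[0] != 0.0:
            raise ValueError("protein_concs must start with the 0 nM control")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError("protein_concs must be strictly ascending")
        if any(c < 0 for c in concs):
            raise ValueError("protein concentrations must be nonnegative")
        if self.depth < 0:
            raise ValueError("depth must be nonnegative")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.pcr_duplication < 1.0:
            raise ValueError("mean PCR duplication must be >= 1")
        object.__setattr__(self, "protein_concs", concs)

    @property
    def labels(self) -> list[str]:
        return [f"lib{i + 1}" for i in range(len(self.protein_concs))]

    def libraries(self) -> pd.DataFrame:
        """Label / index barcode / concentration table for this run."""
        if len(self.protein_concs) > len(INDEX_SEQUENCES):
            raise ValueError(
                f"at most {len(INDEX_SEQUENCES)} libraries supported "
                f"({len(INDEX_SEQUENCES)} index barcodes available)"
            )
        return pd.DataFrame(
            {
                "label": self.labels,
                "index": INDEX_SEQUENCES[: len(self.protein_concs)],
                "conc_nM": self.protein_concs,
            }
        )


def free_fraction(kd: np.ndarray | float, protein_conc: float) -> np.ndarray | float:
    """Unbound fraction kd/(kd+E) under pseudo-first-order binding."""
    if protein_conc < 0:
        raise ValueError(f"protein concentration must be nonnegative, got {protein_conc}")
    return kd / (kd + protein_conc)


def simulate_equilibrium(
    landscape: AffinityLandscape, config: SimulationConfig
) -> pd.DataFrame:
    """Exact unbound-pool composition (nM) per variant per concentration.

    Returns a (variant x library-label) table of expected free-RNA
    concentrations; no sampling noise is introduced at this stage.  At the
    control (E = 0) the composition equals the initial equimolar pool.
    """
    s0 = config.total_rna / len(landscape.variants)
    data = {
        label: s0 * free_fraction(landscape.kd, conc)
        for label, conc in zip(config.labels, config.protein_concs)
    }
    return pd.DataFrame(data, index=pd.Index(landscape.variants, name="variant"))


@dataclass
class ReadSet:
    """Simulated reads as an ASCII matrix plus per-read library assignment.

    ``source_counts`` records the multinomial molecule draws per variant and
    library (before PCR duplication) so downstream counting can be validated
    against the exact sampled truth.
    """

    seqs: np.ndarray  # (n_reads, read_len) uint8 ASCII
    lib: np.ndarray  # (n_reads,) int, index into labels
    labels: list[str]
    layout: ConstructLayout
    source_counts: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.seqs)

    def sequences(self) -> list[str]:
        return [row.tobytes().decode() for row in self.seqs]

    def label_of(self, i: int) -> str:
        return self.labels[self.lib[i]]


def _apply_errors(
    codes: np.ndarray, error_rate: float, rng: np.random.Generator
) -> None:
    """In-place independent per-base substitution errors on base-4 codes."""
    if error_rate <= 0 or codes.size == 0:
        return
    chunk = max(1, 20_000_000 // max(codes.shape[1], 1))
    for start in range(0, len(codes), chunk):
        block = codes[start : start + chunk]
        mask = rng.random(block.shape) < error_rate
        n_err = int(mask.sum())
        if n_err:
            # substitute with one of the three other bases, uniformly
            shift = rng.integers(1, 4, size=n_err, dtype=np.uint8)
            block[mask] = (block[mask] + shift) % 4


def sample_reads(
    composition: pd.DataFrame,
    layout: ConstructLayout | None = None,
    config: SimulationConfig | None = None,
) -> ReadSet:
    """Draw sequencing reads from an unbound-pool composition.

    Per library: ``depth`` source molecules are drawn multinomially from the
    composition, each receives a random 2-nt UMI and the library's 3-nt index
    barcode, is duplicated a geometric number of times (mean
    ``pcr_duplication``), and emitted as a ``read_len`` DNA read
    UMI+index+constant5+7mer+constant3-prefix with independent per-base
    substitution errors.  Deterministic given ``config.seed``.
    """
    layout = layout or ConstructLayout()
    config = config or SimulationConfig()
    if (composition.to_numpy() < 0).any():
        raise ValueError("composition must be nonnegative")
    rng = np.random.default_rng(config.seed)
    labels = list(composition.columns)
    variants = composition.index.to_numpy(dtype="U7")
    kmer_codes = (
        encode_kmers(variants)[:, None]
        // 4 ** np.arange(layout.random_len - 1, -1, -1, dtype=np.int64)[None, :]
        % 4
    ).astype(np.uint8)

    # 'N' slots of the template map to 255 and are overwritten per read below
    template_codes = BASE_CODE[layout.template()]

    if config.depth == 0:
        warnings.warn("depth = 0: returning an empty read set")
        return ReadSet(
            seqs=np.empty((0, layout.read_len), dtype=np.uint8),
            lib=np.empty(0, dtype=np.int64),
            labels=labels,
            layout=layout,
            source_counts=pd.DataFrame(
                0, index=composition.index, columns=labels, dtype=np.int64
            ),
        )

    all_blocks: list[np.ndarray] = []
    all_libs: list[np.ndarray] = []
    counts_table = pd.DataFrame(0, index=composition.index, columns=labels, dtype=np.int64)
    for li, label in enumerate(labels):
        total = composition[label].to_numpy(dtype=float)
        if total.sum() <= 0:
            raise ValueError(f"composition column {label!r} sums to zero")
        p = total / total.sum()
        counts = rng.multinomial(config.depth, p)
        counts_table[label] = counts
        mol_variant = np.repeat(np.arange(len(variants)), counts)
        rng.shuffle(mol_variant)
        umis = rng.integers(0, 4, size=(config.depth, layout.umi_len), dtype=np.uint8)
        if config.pcr_duplication == 1.0:
            dup = np.ones(config.depth, dtype=np.int64)
        else:
            dup = rng.geometric(1.0 / config.pcr_duplication, size=config.depth)
        n_reads = int(dup.sum())
        codes = np.empty((n_reads, layout.read_len), dtype=np.uint8)
        codes[:] = template_codes
        codes[:, : layout.umi_len] = np.repeat(umis, dup, axis=0)
        index_seq = INDEX_SEQUENCES[li % len(INDEX_SEQUENCES)]
        codes[:, layout.umi_len : layout.constant_start] = BASE_CODE[
            np.frombuffer(index_seq.encode(), dtype=np.uint8)
        ]
        codes[:, layout.kmer_start : layout.kmer_end] = kmer_codes[
            np.repeat(mol_variant, dup)
        ]
        _apply_errors(codes, config.error_rate, rng)
        all_blocks.append(CODE_TO_DNA[codes])
        all_libs.append(np.full(n_reads, li, dtype=np.int64))

    return ReadSet(
        seqs=np.concatenate(all_blocks, axis=0),
        lib=np.concatenate(all_libs),
        labels=labels,
        layout=layout,
        source_counts=counts_table,
    )


def write_fastq(reads: ReadSet, path) -> None:
    """Write a read set as plain 4-line FASTQ records (fixed 'I' qualities)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    qual = "I" * reads.layout.read_len
    try:
        with opener(path, "wt") as fh:
            for i in range(len(reads)):
                fh.write(
                    f"@read{i} lib={reads.labels[reads.lib[i]]}\n"
                    f"{reads.seqs[i].tobytes().decode()}\n+\n{qual}\n"
                )
    except OSError as exc:
        raise OSError(f"failed to write FASTQ to {path}: {exc}") from exc
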