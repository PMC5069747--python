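"""Synthetic genomes, count tables and spectra with known ground truth.

Every stage of the pipeline is testable offline against data from this
module: genomes carry a configurable set of pucBA operons (beta then alpha
in transcription order, random strand, short intra-operon gap) embedded in
random intergenic DNA; count tables emulate two-condition (high light /
low light) transcriptomes in which LH genes dominate the transcriptome and
the LH3/LH4 genes are low-light-induced; spectra are noisy Gaussian
mixtures over the diagnostic near-infrared bands.  All generators are
deterministic per seed, and a zero-noise / zero-substitution configuration
makes every downstream stage's output equal the truth table exactly.

The reference peptides produced by :func:`make_reference_set` are synthetic
stand-ins constructed to satisfy the field's descriptive constraints
(alpha 60-65 aa with class signatures at positions 26/44/45; beta ~50 aa,
>90% mutually identical; LH2 subtypes <85% mutually identical) — they are
not database sequences.  Real-data runs should supply a reference FASTA of
the reference strain's peptides instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import SIGNATURE_POSITIONS, classify_alpha, SignatureProfile
from .discovery import ReferencePeptide
from .io import GeneFeature, SeqRecord
from .spectra import BAND_CATALOG, Spectrum

ALPHA_LENGTH = 62
BETA_LENGTH = 50
LH_CLASSES = ("LH2A", "LH2B", "LH2E", "LH3", "LH4", "LH2prime")

#: signature residues (positions 26, 44, 45) planted per class
CLASS_SIGNATURES = {
    "LH2A": ("A", "Y", "W"),
    "LH2B": ("A", "Y", "W"),
    "LH2E": ("A", "Y", "W"),
    "LH3": ("A", "F", "M"),
    "LH4": ("M", "F", "M"),
    "LH2prime": ("A", "Y", "M"),
}

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: standard-code codons per amino acid (bacterial table; no stops)
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"], "L": ["CTT", "CTC", "CTA", "CTG", "TTA", "TTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}

STOP_CODON = "TAA"


@dataclass
class ReferenceSet:
    """Labelled stand-in alpha/beta reference peptides with coding sequences."""

    alphas: dict[str, ReferencePeptide]
    betas: dict[str, ReferencePeptide]

    @property
    def reference_alpha(self) -> str:
        """The LH2A alpha peptide anchoring the signature numbering frame."""
        return self.alphas["LH2A"].peptide

    @property
    def subtype_references(self) -> dict[str, str]:
        return {sub: self.alphas[sub].peptide for sub in ("LH2A", "LH2B", "LH2E")}

    def as_list(self) -> list[ReferencePeptide]:
        return list(self.alphas.values()) + list(self.betas.values())

    def cds_by_id(self) -> dict[str, str]:
        return {r.id: r.cds for r in self.as_list() if r.cds}


def _mutate_positions(rng, peptide: list[str], k: int, protected: set[int]) -> list[str]:
    """Substitute k distinct unprotected positions with different residues."""
    free = [i for i in range(len(peptide)) if i not in protected]
    for i in rng.choice(free, size=k, replace=False):
        choices = [a for a in _AA20 if a != peptide[i] and a != "M"]
        peptide[i] = choices[rng.integers(len(choices))]
    return peptide


def _back_translate(rng, peptide: str, start_met: bool = True) -> str:
    codons = []
    for idx, aa in enumerate(peptide):
        if idx == 0 and start_met:
            codons.append("ATG")
            continue
        options = _CODONS[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons) + STOP_CODON


def make_reference_set(seed: int) -> ReferenceSet:
    """Generate internally consistent stand-in reference peptides and CDS.

    Alphas are 62 aa with the class signature planted at reference positions
    26/44/45 (the LH2 subtypes share the LH2 signature but differ at >=15%
    of other positions); betas are 50 aa and mutually >90% identical.
    Deterministic per seed.
    """
    rng = np.random.default_rng([int(seed), 0])
    sig_idx = {p - 1 for p in SIGNATURE_POSITIONS}
    protected = sig_idx | {0}
    base_alpha = ["M"] + [
        _AA20[rng.integers(len(_AA20))] for _ in range(ALPHA_LENGTH - 1)
    ]
    for i in range(1, ALPHA_LENGTH):  # avoid stray M26-like marks elsewhere
        if base_alpha[i] == "M":
            base_alpha[i] = "L"
    divergence = {"LH2A": 0, "LH2B": 12, "LH2E": 12, "LH3": 9, "LH4": 9,
                  "LH2prime": 9}
    alphas: dict[str, ReferencePeptide] = {}
    for cls in LH_CLASSES:
        pep = list(base_alpha)
        if divergence[cls]:
            pep = _mutate_positions(rng, pep, divergence[cls], protected)
        for pos, residue in zip(SIGNATURE_POSITIONS, CLASS_SIGNATURES[cls]):
            pep[pos - 1] = residue
        peptide = "".join(pep)
        profile = SignatureProfile(peptide[25], peptide[43], peptide[44])
        expected = "LH2" if cls.startswith("LH2") and cls not in ("LH2prime",) else cls
        assert classify_alpha(profile) == ("LH2" if cls in ("LH2A", "LH2B", "LH2E")
                                           else cls), (cls, profile)
        cds = _back_translate(rng, peptide)
        alphas[cls] = ReferencePeptide(
            id=f"ref_pucA_{cls}", role="alpha", peptide=peptide, cds=cds, lh_class=cls
        )
    base_beta = ["M"] + [_AA20[rng.integers(len(_AA20))] for _ in range(BETA_LENGTH - 1)]
    betas: dict[str, ReferencePeptide] = {}
    for cls in LH_CLASSES:
        pep = list(base_beta)
        pep = _mutate_positions(rng, pep, 2, {0})
        peptide = "".join(pep)
        cds = _back_translate(rng, peptide)
        betas[cls] = ReferencePeptide(
            id=f"ref_pucB_{cls}", role="beta", peptide=peptide, cds=cds, lh_class=cls
        )
    return ReferenceSet(alphas, betas)


# ---------------------------------------------------------------------------
# Genome generation


@dataclass
class OperonSpec:
    """One planted operon: its LH class and optional lesions."""

    lh_class: str
    pseudogene: bool = False
    lone_alpha: bool = False

    def __post_init__(self) -> None:
        if self.lh_class not in LH_CLASSES:
            raise ValueError(f"unknown LH class {self.lh_class!r}")


@dataclass
class GeneratorConfig:
    """Everything the generators need; the seed is mandatory.

    Default expression targets follow the field's reported magnitudes: the
    bulk of the transcriptome sits at 50-250 rpkm while LH genes reach the
    10^3-10^5 range, with the LH3/LH4 operons strongly low-light-induced.
    """

    seed: int
    operons: list[OperonSpec] = field(default_factory=list)
    substitution_rate: float = 0.0
    protect_signatures: bool = True
    intergenic_mean: int = 500
    gap_range: tuple[int, int] = (5, 60)
    strain: str = "synthetic_strain"
    intact_only: bool = False
    # count-table parameters
    class_rpkm: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_RPKM))
    background_rpkm_range: tuple[float, float] = (50.0, 250.0)
    n_background: int = 200
    background_length_range: tuple[int, int] = (300, 3000)
    dispersion: float = 0.1
    library_size: int = 5_000_000
    replicates: int = 2
    conditions: tuple[str, ...] = ("HL", "LL")
    # spectrum parameters
    spectrum_complexes: tuple[str, ...] = ("LH2",)
    band_sigma: float = 8.0
    band_amplitude: float = 1.0
    noise_sd: float = 0.01
    grid_nm: tuple[float, float, float] = (700.0, 950.0, 1.0)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        if self.intact_only and any(op.pseudogene for op in self.operons):
            raise ValueError("config demands intact genes but plants a pseudogene")


#: per (class, role) mean rpkm targets by condition, patterned on the
#: reported LH transcript magnitudes (LL-induced LH3/LH4, dominant LH2A)
DEFAULT_CLASS_RPKM = {
    ("LH2A", "alpha"): {"HL": 38_019.0, "LL": 24_466.0},
    ("LH2A", "beta"): {"HL": 346_456.0, "LL": 215_767.0},
    ("LH2B", "alpha"): {"HL": 2_891.0, "LL": 2_207.0},
    ("LH2B", "beta"): {"HL": 1_389.0, "LL": 1_033.0},
    ("LH2E", "alpha"): {"HL": 4_125.0, "LL": 2_332.0},
    ("LH2E", "beta"): {"HL": 2_445.0, "LL": 1_662.0},
    ("LH3", "alpha"): {"HL": 650.0, "LL": 30_000.0},
    ("LH3", "beta"): {"HL": 5_819.0, "LL": 279_889.0},
    ("LH4", "alpha"): {"HL": 656.0, "LL": 32_046.0},
    ("LH4", "beta"): {"HL": 2_996.0, "LL": 156_693.0},
    ("LH2prime", "alpha"): {"HL": 2_900.0, "LL": 2_200.0},
    ("LH2prime", "beta"): {"HL": 1_400.0, "LL": 1_050.0},
}


@dataclass
class TruthGene:
    gene_id: str
    operon_index: int
    role: str
    lh_class: str
    start: int
    end: int
    strand: str
    pseudogene: bool
    cds: str
    length_bp: int


@dataclass
class TruthTable:
    """Ground truth that fully determines expected pipeline output at rate 0."""

    genes: list[TruthGene]
    seed: int
    strain: str
    operons: list[OperonSpec]

    def expected_inventory(self) -> dict:
        """The inventory row this genome should produce: pucB count plus
        intact/pseudo counts per category."""
        intact = {c: 0 for c in LH_CLASSES}
        pseudo = {c: 0 for c in LH_CLASSES}
        pucb = sum(1 for op in self.operons if not op.lone_alpha)
        for op in self.operons:
            (pseudo if op.pseudogene else intact)[op.lh_class] += 1
        return dict(pucB=pucb, intact=intact, pseudo=pseudo,
                    lone=sum(1 for op in self.operons if op.lone_alpha))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(g) for g in self.genes])


_BASES = np.array(list("ACGT"))


def _random_dna(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, size=max(length, 0)))


def _intergenic(rng, mean: int) -> str:
    length = 50 + rng.geometric(1.0 / max(mean - 50, 1))
    return _random_dna(rng, length)


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]


def _protected_nt(role: str, cds_len: int, protect: bool) -> set[int]:
    """Nucleotide positions spared from substitution: the signature codons
    of alphas plus the start and stop codons (so the planted truth stays
    recoverable at low rates)."""
    if not protect:
        return set()
    idx = set(range(3)) | set(range(cds_len - 3, cds_len))
    if role == "alpha":
        for pos in SIGNATURE_POSITIONS:
            idx |= set(range(3 * (pos - 1), 3 * pos))
    return idx


def _mutate_cds(rng, cds: str, rate: float, protected: set[int]) -> str:
    if rate <= 0:
        return cds
    out = list(cds)
    hits = rng.random(len(out)) < rate
    for i in np.nonzero(hits)[0]:
        if int(i) in protected:
            continue
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[rng.integers(3)]
    return "".join(out)


def _plant_frameshift(cds: str, insert_codon: int = 20, insert: str = "GG") -> str:
    """Insert a 2-bp run inside the coding sequence (classic pseudogene lesion)."""
    pos = 3 * insert_codon
    return cds[:pos] + insert + cds[pos:]


def generate_genome(
    config: GeneratorConfig,
    refs: ReferenceSet | None = None,
) -> tuple[SeqRecord, list[GeneFeature], TruthTable]:
    """Embed the configured operons in random DNA; return genome + truth.

    Operons are laid out beta-then-alpha in transcription order with a gap
    drawn from ``config.gap_range``, on a random strand, separated by
    geometric-length intergenic DNA of uniform base composition.  A
    pseudogene spec plants a 2-bp insertion in the alpha coding sequence.
    Substitutions are applied per site at ``substitution_rate``, sparing
    signature codons and gene boundaries when ``protect_signatures``.
    """
    refs = refs or make_reference_set(config.seed)
    rng = np.random.default_rng([int(config.seed), 1])
    pieces: list[str] = []
    cursor = 0
    truth: list[TruthGene] = []
    features: list[GeneFeature] = []

    def push(seq: str) -> int:
        nonlocal cursor
        pieces.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    push(_intergenic(rng, config.intergenic_mean))
    for op_idx, spec in enumerate(config.operons):
        strand = "+" if rng.random() < 0.5 else "-"
        alpha_cds = refs.alphas[spec.lh_class].cds
        beta_cds = refs.betas[spec.lh_class].cds
        if spec.pseudogene:
            alpha_cds = _plant_frameshift(alpha_cds)
        alpha_cds = _mutate_cds(
            rng, alpha_cds, config.substitution_rate,
            _protected_nt("alpha", len(alpha_cds), config.protect_signatures),
        )
        beta_cds = _mutate_cds(
            rng, beta_cds, config.substitution_rate,
            _protected_nt("beta", len(beta_cds), config.protect_signatures),
        )
        gap = int(rng.integers(config.gap_range[0], config.gap_range[1] + 1))
        gap_dna = _random_dna(rng, gap)
        segment_genes = []  # (local_start, local_end, role, cds)
        local = 0
        if not spec.lone_alpha:
            segment_genes.append((local, local + len(beta_cds), "beta", beta_cds))
            local += len(beta_cds)
            segment = beta_cds + gap_dna
            local += gap
        else:
            segment = ""
        segment_genes.append((local, local + len(alpha_cds), "alpha", alpha_cds))
        segment = segment + alpha_cds
        if strand == "-":
            seg_len = len(segment)
            segment = _revcomp(segment)
            segment_genes = [
                (seg_len - e, seg_len - s, role, cds)
                for s, e, role, cds in segment_genes
            ]
        offset = push(segment)
        for s, e, role, cds in segment_genes:
            gene_id = f"{config.strain}_{op_idx + 1:02d}{'A' if role == 'alpha' else 'B'}"
            truth.append(TruthGene(
                gene_id=gene_id, operon_index=op_idx, role=role,
                lh_class=spec.lh_class, start=offset + s, end=offset + e,
                strand=strand,
                pseudogene=spec.pseudogene and role == "alpha",
                cds=cds, length_bp=e - s,
            ))
            features.append(GeneFeature(
                contig_id=config.strain, start=offset + s, end=offset + e,
                strand=strand, feature_type="CDS",
                attributes={"ID": gene_id, "locus_tag": gene_id},
            ))
        push(_intergenic(rng, config.intergenic_mean))
    genome = SeqRecord(config.strain, f"{config.strain} synthetic genome",
                       "".join(pieces), "nucleotide")
    return genome, features, TruthTable(truth, config.seed, config.strain,
                                        list(config.operons))


# ---------------------------------------------------------------------------
# Count tables


def _nb_draw(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative binomial with variance mean + dispersion * mean^2."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion < 1e-8:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def generate_counts(
    config: GeneratorConfig, truth: TruthTable
) -> tuple[pd.DataFrame, pd.Series, dict[str, str], pd.DataFrame]:
    """Two-condition replicate count table for LH plus background genes.

    Counts are negative-binomial draws at the mean implied by each gene's
    target rpkm, its length and the library size.  Returns (counts,
    library sizes, sample->condition map, per-gene expression truth).
    """
    rng = np.random.default_rng([int(config.seed), 2])
    genes = []  # (gene_id, length, {condition: target_rpkm}, category)
    for g in truth.genes:
        targets = config.class_rpkm.get((g.lh_class, g.role))
        if targets is None:
            raise KeyError(f"no rpkm target for ({g.lh_class}, {g.role})")
        genes.append((g.gene_id, g.length_bp, dict(targets), g.lh_class))
    lo, hi = config.background_rpkm_range
    for b in range(config.n_background):
        length = int(rng.integers(*config.background_length_range))
        targets = {c: float(rng.uniform(lo, hi)) for c in config.conditions}
        genes.append((f"bg_{b + 1:04d}", length, targets, "background"))
    samples = [f"{c}_r{r + 1}" for c in config.conditions
               for r in range(config.replicates)]
    sample_condition = {s: s.rsplit("_r", 1)[0] for s in samples}
    lib = float(config.library_size)
    data = {}
    for sample in samples:
        cond = sample_condition[sample]
        col = []
        for _, length, targets, _cat in genes:
            mean = targets[cond] * (length / 1000.0) * (lib / 1e6)
            col.append(int(_nb_draw(rng, mean, config.dispersion, 1)[0]))
        data[sample] = col
    index = [g[0] for g in genes]
    counts = pd.DataFrame(data, index=pd.Index(index, name="gene"))
    libsizes = pd.Series({s: lib for s in samples}, name="library_size")
    truth_rows = [
        dict(gene=gid, length_bp=length, category=cat,
             **{f"rpkm_{c}": t[c] for c in config.conditions})
        for gid, length, t, cat in genes
    ]
    return counts, libsizes, sample_condition, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Spectra


def generate_spectrum(config: GeneratorConfig) -> tuple[Spectrum, list[str]]:
    """Noisy Gaussian mixture over the diagnostic bands of the configured
    complexes, on a 1-nm grid (700-950 nm by default)."""
    rng = np.random.default_rng([int(config.seed), 3])
    lo, hi, step = config.grid_nm
    wl = np.arange(lo, hi + step / 2, step)
    trace = np.zeros_like(wl)
    for name in config.spectrum_complexes:
        for band in BAND_CATALOG[name]:
            trace += config.band_amplitude * np.exp(
                -0.5 * ((wl - band) / config.band_sigma) ** 2
            )
    if config.noise_sd > 0:
        trace = trace + rng.normal(0.0, config.noise_sd, size=wl.shape)
    return Spectrum(wl, trace), sorted(set(config.spectrum_complexes))


# ---------------------------------------------------------------------------
# Canned study-pattern configs


def cga009_pattern(seed: int, **overrides) -> GeneratorConfig:
    """The reference-strain pattern: three LH2 operons (A, B, E), a
    pseudogene LH3 operon (2-bp insertion) and an LH4 operon."""
    operons = [
        OperonSpec("LH2A"), OperonSpec("LH2B"), OperonSpec("LH2E"),
        OperonSpec("LH3", pseudogene=True), OperonSpec("LH4"),
    ]
    return GeneratorConfig(seed=seed, operons=operons, strain="synthetic_CGA009",
                           **overrides)


def dx1_pattern(seed: int, **overrides) -> GeneratorConfig:
    """The LH2-only pattern: three LH2 operons, no LH3 or LH4."""
    operons = [OperonSpec("LH2A"), OperonSpec("LH2B"), OperonSpec("LH2E")]
    return GeneratorConfig(seed=seed, operons=operons, strain="synthetic_DX1",
                           **overrides)
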