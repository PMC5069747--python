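"""Discovery of pucB/pucA coding sequences and pairing into pucBA operons.

The alpha peptides of LH2-like complexes are 60-65 aa and the beta peptides
about 50 aa, so candidate ORFs are collected in a widened 40-75 aa window
(tolerant of divergent strains) and scored by global-alignment identity
against a labelled reference set of alpha/beta peptides.  An ORF becomes a
PucGene when its best identity reaches the calling threshold (default 0.60:
beta peptides are >90% identical within the genus, so this admits divergent
clades while excluding random ORFs).  Betas are then paired with the nearest
downstream alpha on the same strand (gap <= 300 bp by default, beta upstream
per the pucBA transcription order); alphas with no beta partner are emitted
as lone-alpha operons, mirroring the one strain whose eighth pucA lacks a
tandem pucB.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

from . import align
from .io import GeneFeature, SeqRecord, internal_to_external

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
TRANSLATION_TABLE = 11  # standard bacterial code

DEFAULT_MIN_AA = 40
DEFAULT_MAX_AA = 75
ALPHA_LENGTH_WINDOW = (55, 75)
BETA_LENGTH_WINDOW = (40, 60)
DEFAULT_IDENTITY_THRESHOLD = 0.60
DEFAULT_MAX_GAP = 300


@dataclass
class Orf:
    """A located open reading frame (internal coordinates, stop included)."""

    contig_id: str
    start: int
    end: int
    strand: str
    cds: str
    peptide: str


@dataclass
class ReferencePeptide:
    """A labelled reference peptide, optionally with its coding sequence."""

    id: str
    role: str  # 'alpha' | 'beta'
    peptide: str
    cds: str | None = None
    lh_class: str | None = None


@dataclass
class PucGene:
    """A candidate LH alpha or beta gene with its best reference hit."""

    contig_id: str
    start: int
    end: int
    strand: str
    role: str
    cds: str
    peptide: str
    best_ref_id: str
    best_ref_identity: float
    gene_id: str = ""

    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class Operon:
    """A pucBA unit: beta (optional) followed by alpha in transcription order."""

    alpha: PucGene
    beta: PucGene | None = None
    gap_bp: int = -1
    id: str = ""

    @property
    def lone_alpha(self) -> bool:
        return self.beta is None


def translate_cds(cds: str) -> str:
    """Conceptual translation under the bacterial code, stop codon stripped."""
    peptide = str(Seq(cds).translate(table=TRANSLATION_TABLE))
    if peptide.endswith("*"):
        peptide = peptide[:-1]
    return peptide


def find_orfs(genome: SeqRecord, min_aa: int, max_aa: int) -> list[Orf]:
    """All ORFs on both strands with peptide length in [min_aa, max_aa].

    An ORF runs from a start codon (ATG/GTG/TTG) to the first in-frame stop;
    the stop codon is part of the reported interval.  Nested ORFs sharing a
    stop but using different start codons are all reported.
    """
    if genome.alphabet != "nucleotide":
        raise TypeError("find_orfs requires a nucleotide genome")
    if not (0 < min_aa <= max_aa):
        raise ValueError("need 0 < min_aa <= max_aa")
    n = len(genome.sequence)
    results: list[Orf] = []
    for strand in "+-":
        seq = genome.sequence if strand == "+" else str(
            Seq(genome.sequence).reverse_complement()
        )
        for frame in range(3):
            stops = [
                i for i in range(frame, n - 2, 3) if seq[i:i + 3] in STOP_CODONS
            ]
            for i in range(frame, n - 2, 3):
                if seq[i:i + 3] not in START_CODONS:
                    continue
                k = bisect_right(stops, i)
                if k == len(stops):
                    continue
                stop = stops[k]
                aa_len = (stop - i) // 3
                if not (min_aa <= aa_len <= max_aa):
                    continue
                cds = seq[i:stop + 3]
                s, e = i, stop + 3
                if strand == "-":
                    s, e = n - e, n - s
                results.append(
                    Orf(genome.id, s, e, strand, cds, translate_cds(cds))
                )
    results.sort(key=lambda o: (o.start, o.end, o.strand))
    return results


def score_candidate(
    peptide: str,
    reference_set: Sequence[ReferencePeptide],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> tuple[str, float, str | None]:
    """Best reference hit for a candidate peptide.

    Returns (best_ref_id, identity, role); role is None below *threshold*.
    Identity is exact matches over the full global-alignment length (with
    affine gaps), so fragments are penalized for the reference they miss.
    """
    if not reference_set:
        raise ValueError("reference set is empty")
    best_id, best_identity, best_role = "", -1.0, None
    for ref in reference_set:
        ident = align.pairwise_identity_global(peptide, ref.peptide, "protein")
        if ident > best_identity:
            best_id, best_identity, best_role = ref.id, ident, ref.role
    role = best_role if best_identity >= threshold else None
    return best_id, best_identity, role


def pair_operons(
    puc_genes: Iterable[PucGene],
    max_gap: int = DEFAULT_MAX_GAP,
) -> tuple[list[Operon], list[PucGene]]:
    """Pair betas with the nearest downstream alpha into pucBA operons.

    Downstream means in transcription orientation: on '+' the alpha starts
    after the beta ends; on '-' the alpha ends before the beta starts.  Each
    gene joins at most one operon.  Unpaired alphas become lone-alpha
    operons; unpaired betas are returned separately as flagged.
    """
    genes = list(puc_genes)
    alphas = [g for g in genes if g.role == "alpha"]
    betas = [g for g in genes if g.role == "beta"]
    claimed: set[int] = set()
    operons: list[Operon] = []
    unpaired_betas: list[PucGene] = []

    for beta in sorted(betas, key=lambda g: g.start):
        best = None
        best_gap = None
        for idx, alpha in enumerate(alphas):
            if idx in claimed:
                continue
            if alpha.contig_id != beta.contig_id or alpha.strand != beta.strand:
                continue
            if beta.strand == "+":
                gap = alpha.start - beta.end
            else:
                gap = beta.start - alpha.end
            if gap < 0 or gap > max_gap:
                continue
            if best_gap is None or gap < best_gap:
                best, best_gap = idx, gap
        if best is None:
            unpaired_betas.append(beta)
        else:
            claimed.add(best)
            operons.append(Operon(alpha=alphas[best], beta=beta, gap_bp=best_gap))
    for idx, alpha in enumerate(alphas):
        if idx not in claimed:
            operons.append(Operon(alpha=alpha, beta=None, gap_bp=-1))
    operons.sort(key=lambda o: (o.alpha.contig_id, min(
        o.alpha.start, o.beta.start if o.beta else o.alpha.start)))
    for i, op in enumerate(operons, 1):
        op.id = f"pucBA_{i:02d}"
        op.alpha.gene_id = op.alpha.gene_id or f"{op.id}_A"
        if op.beta:
            op.beta.gene_id = op.beta.gene_id or f"{op.id}_B"
    return operons, unpaired_betas


def _score_nucleotide(
    cds: str,
    reference_set: Sequence[ReferencePeptide],
    threshold: float,
) -> tuple[str, float, str | None]:
    """Nucleotide-level fallback scoring against reference coding sequences."""
    best_id, best_identity, best_role = "", -1.0, None
    for ref in reference_set:
        if not ref.cds:
            continue
        ident = align.pairwise_identity_global(cds, ref.cds, "nucleotide")
        if ident > best_identity:
            best_id, best_identity, best_role = ref.id, ident, ref.role
    role = best_role if best_identity >= threshold else None
    return best_id, best_identity, role


def _extract_feature_cds(genome: SeqRecord, feature: GeneFeature) -> str:
    cds = genome.sequence[feature.start:feature.end]
    if feature.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def discover_puc_genes(
    genome: SeqRecord,
    reference_set: Sequence[ReferencePeptide],
    features: Sequence[GeneFeature] | None = None,
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    min_aa: int = DEFAULT_MIN_AA,
    max_aa: int = DEFAULT_MAX_AA,
) -> list[PucGene]:
    """Find candidate LH genes by annotation scoring and/or ORF scanning.

    Annotated CDS features (when supplied) are scored directly; ORF scanning
    covers the rest of the genome.  Nested ORFs ending at the same stop are
    collapsed to the best-scoring start.
    """
    candidates: list[tuple[Orf, str, float, str]] = []
    annotated_spans: list[tuple[int, int, str]] = []
    if features:
        for feat in features:
            if feat.feature_type != "CDS":
                continue
            cds = _extract_feature_cds(genome, feat)
            if len(cds) < 3 * min_aa:
                continue
            frame_cds = cds[: len(cds) - len(cds) % 3]
            peptide = translate_cds(frame_cds).rstrip("*")
            conceptual = peptide.split("*")[0]  # product up to a premature stop
            annotated_spans.append((feat.start, feat.end, feat.strand))
            if not conceptual:
                continue
            ref_id, ident, role = score_candidate(conceptual, reference_set, threshold)
            if role is None:
                # disrupted genes (frameshifts) can be unrecognizable at the
                # peptide level yet near-identical at the nucleotide level
                ref_id, ident, role = _score_nucleotide(cds, reference_set, threshold)
            if role:
                candidates.append(
                    (Orf(genome.id, feat.start, feat.end, feat.strand, cds, conceptual),
                     ref_id, ident, role)
                )
    for orf in find_orfs(genome, min_aa, max_aa):
        if any(s <= orf.start and orf.end <= e and orf.strand == st
               for s, e, st in annotated_spans):
            continue  # annotated regions are scored through their annotation
        ref_id, ident, role = score_candidate(orf.peptide, reference_set, threshold)
        if role:
            candidates.append((orf, ref_id, ident, role))
    # collapse nested starts sharing a stop: keep the best identity
    by_stop: dict[tuple[str, str, int], tuple[Orf, str, float, str]] = {}
    for orf, ref_id, ident, role in candidates:
        key = (orf.contig_id, orf.strand, orf.end if orf.strand == "+" else orf.start)
        if key not in by_stop or ident > by_stop[key][2]:
            by_stop[key] = (orf, ref_id, ident, role)
    genes = [
        PucGene(orf.contig_id, orf.start, orf.end, orf.strand, role,
                orf.cds, orf.peptide, ref_id, ident)
        for orf, ref_id, ident, role in by_stop.values()
    ]
    genes.sort(key=lambda g: (g.contig_id, g.start))
    return genes


def genes_to_table_rows(operons: Sequence[Operon], unpaired: Sequence[PucGene]):
    """Rows for the per-gene TSV (1-based external coordinates)."""
    rows = []
    for op in operons:
        for gene in filter(None, (op.beta, op.alpha)):
            s1, e1 = internal_to_external(gene.start, gene.end)
            rows.append(dict(
                gene_id=gene.gene_id, operon_id=op.id, contig=gene.contig_id,
                start=s1, end=e1, strand=gene.strand, role=gene.role,
                best_ref=gene.best_ref_id,
                identity=round(gene.best_ref_identity, 4),
                gap_bp=op.gap_bp if gene.role == "alpha" else "",
                lone_alpha=op.lone_alpha if gene.role == "alpha" else "",
            ))
    for gene in unpaired:
        s1, e1 = internal_to_external(gene.start, gene.end)
        rows.append(dict(
            gene_id=gene.gene_id or "unpaired_beta", operon_id="", contig=gene.contig_id,
            start=s1, end=e1, strand=gene.strand, role=gene.role,
            best_ref=gene.best_ref_id, identity=round(gene.best_ref_identity, 4),
            gap_bp="", lone_alpha="",
        ))
    return rows
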