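"""Signature-residue classification of LH alpha peptides and inventories.

Four peripheral LH complex types are distinguished by two or three residues
of the alpha peptide, numbered in the reference LH2A alpha coordinate frame:

=========  =====================  =========================
type       absorption bands (nm)  alpha signature
=========  =====================  =========================
LH2        800 and 850 (860 in    Y44, W45
           whole cells)
LH2'       800 and 840            Y44, M45
LH3        800 and 820            F44 with M45 or F45
LH4        800                    M26, F44, M45
=========  =====================  =========================

LH4 takes precedence over LH3 (the LH3 pattern F44/M45 is a subset of the
LH4 pattern; the M26 mark separates them).  LH2 genes are further split into
the paralogous LH2A/LH2B/LH2E sets by whole-peptide identity to the
reference strain's three LH2 alphas.  Pseudogenes are called from a
frameshifting indel (net indel length not divisible by three against the
reference coding sequence) or a premature internal stop; a pseudogene still
receives a type from its conceptual translation where the signature is
readable, but is excluded from intact inventory counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import align
from .discovery import Operon, ReferencePeptide, translate_cds

GAP = "-"
SIGNATURE_POSITIONS = (26, 44, 45)  # 1-based, reference alpha frame
LH_TYPES = ("LH2", "LH2prime", "LH3", "LH4", "unclassified")
LH2_SUBTYPES = ("LH2A", "LH2B", "LH2E")
INVENTORY_CATEGORIES = ("LH2A", "LH2B", "LH2E", "LH3", "LH4", "LH2prime")

#: beta genes inherit the category of their operon's alpha
BETA_CATEGORY = {
    "LH2A": "pucBa",
    "LH2B": "pucBb",
    "LH3": "pucBc",
    "LH4": "pucBd",
    "LH2E": "pucBe",
}

MIN_NUMBERING_IDENTITY = 0.3
PREMATURE_STOP_FRACTION = 0.9


class NumberingError(ValueError):
    """Alignment to the reference alpha too weak to transfer numbering."""


@dataclass(frozen=True)
class SignatureProfile:
    """Residues observed at reference alpha positions 26, 44 and 45."""

    residue_26: str
    residue_44: str
    residue_45: str

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.residue_26, self.residue_44, self.residue_45)


@dataclass
class PseudogeneEvidence:
    kind: str = "none"  # 'none' | 'frameshift_indel_bp' | 'premature_stop_at'
    value: int = 0


@dataclass
class LHCall:
    """Full classification record for one alpha gene."""

    lh_type: str
    lh2_subtype: str = "none"
    signature: SignatureProfile | None = None
    pseudogene: bool = False
    evidence: PseudogeneEvidence = field(default_factory=PseudogeneEvidence)
    subtype_identity: float = 0.0
    tie_flag: bool = False


def number_positions(alpha_peptide: str, reference_alpha: str) -> SignatureProfile:
    """Read the residues aligned to reference positions 26/44/45.

    The peptide is globally aligned to the reference alpha; insertions in
    the peptide are absorbed by the alignment and deletions produce the gap
    marker.  Raises NumberingError when alignment identity is below 0.3,
    i.e. the peptide is unlikely to be an LH alpha at all.
    """
    if not alpha_peptide or not reference_alpha:
        raise ValueError("peptides must be non-empty")
    alignment = align.align_pair(reference_alpha, alpha_peptide, "protein")
    if align.identity(alignment) < MIN_NUMBERING_IDENTITY:
        raise NumberingError(
            "alignment identity below 0.3; numbering unreliable (not an LH alpha?)"
        )
    ref_row, pep_row = alignment[0], alignment[1]
    wanted = {}
    ref_pos = 0
    for ref_char, pep_char in zip(ref_row, pep_row):
        if ref_char != GAP:
            ref_pos += 1
            if ref_pos in SIGNATURE_POSITIONS:
                wanted[ref_pos] = pep_char if pep_char != GAP else GAP
    profile = [wanted.get(pos, GAP) for pos in SIGNATURE_POSITIONS]
    return SignatureProfile(*profile)


def classify_alpha(profile: SignatureProfile) -> str:
    """Map a signature profile to an LH type.

    Total and deterministic; precedence makes the four signature rows
    mutually exclusive (LH4's M26 mark separates it from LH3).
    """
    r26, r44, r45 = profile.as_tuple()
    if r44 == "Y" and r45 == "W":
        return "LH2"
    if r44 == "Y" and r45 == "M":
        return "LH2prime"
    if r26 == "M" and r44 == "F" and r45 == "M":
        return "LH4"
    if r44 == "F" and r45 in ("M", "F") and r26 != "M":
        return "LH3"
    return "unclassified"


def assign_lh2_subtype(
    alpha_peptide: str,
    subtype_references: Mapping[str, str],
) -> tuple[str, float, bool]:
    """Pick the LH2 subtype of maximal global-alignment identity.

    *subtype_references* maps LH2A/LH2B/LH2E to the reference strain's alpha
    peptides.  Ties break lexicographically (A < B < E) with tie_flag set.
    """
    missing = [s for s in LH2_SUBTYPES if s not in subtype_references]
    if missing:
        raise ValueError(f"missing LH2 subtype reference(s): {missing}")
    identities = {
        sub: align.pairwise_identity(alpha_peptide, subtype_references[sub], "protein")
        for sub in LH2_SUBTYPES
    }
    best = max(identities.values())
    winners = [s for s in LH2_SUBTYPES if identities[s] == best]
    return winners[0], best, len(winners) > 1


def detect_pseudogene(
    cds: str, reference_cds: str
) -> tuple[bool, PseudogeneEvidence]:
    """Call a pseudogene from a frameshifting indel or a premature stop.

    A gene is a pseudogene when (a) the net indel length implied by a global
    nucleotide alignment to the reference coding sequence is not divisible
    by three (reading frame shifted), or (b) conceptual translation hits an
    internal stop before 90% of the reference peptide length.
    """
    if len(reference_cds) < 30:
        raise ValueError("reference CDS shorter than 30 nt")
    alignment = align.align_pair(reference_cds, cds, "nucleotide")
    ref_row, cds_row = alignment[0], alignment[1]
    insertions = sum(1 for r, c in zip(ref_row, cds_row) if r == GAP and c != GAP)
    deletions = sum(1 for r, c in zip(ref_row, cds_row) if c == GAP and r != GAP)
    net_indel = insertions - deletions
    if net_indel % 3 != 0:
        return True, PseudogeneEvidence("frameshift_indel_bp", net_indel)
    from Bio.Seq import Seq

    peptide = str(Seq(cds[: len(cds) - len(cds) % 3]).translate(table=11))
    ref_aa_len = len(reference_cds) // 3 - 1  # stop codon excluded
    stop_idx = peptide.find("*")
    if stop_idx != -1 and stop_idx + 1 < len(peptide):  # internal, not terminal
        codon_number = stop_idx + 1
        if codon_number < PREMATURE_STOP_FRACTION * ref_aa_len:
            return True, PseudogeneEvidence("premature_stop_at", codon_number)
    return False, PseudogeneEvidence("none", 0)


def categorize_beta(operon: Operon, alpha_call: LHCall) -> str | None:
    """Category of a beta gene, inherited from its operon's alpha.

    Returns None for lone-alpha operons (nothing to categorize);
    'uncategorized' when the alpha itself is unclassified or has no
    beta-category convention (LH2').
    """
    if operon.beta is None:
        return None
    key = alpha_call.lh2_subtype if alpha_call.lh_type == "LH2" else alpha_call.lh_type
    return BETA_CATEGORY.get(key, "uncategorized")


@dataclass
class OperonCall:
    """Classification of one operon: the alpha's LHCall plus beta category."""

    operon: Operon
    call: LHCall
    beta_category: str | None

    @property
    def category(self) -> str:
        if self.call.lh_type == "LH2":
            return self.call.lh2_subtype
        return self.call.lh_type


def classify_operon(
    operon: Operon,
    reference_alpha: str,
    subtype_references: Mapping[str, str],
    reference_cds_by_id: Mapping[str, str] | None = None,
) -> OperonCall:
    """Run numbering, typing, subtyping and pseudogene detection on an operon.

    *reference_alpha* anchors the signature numbering frame (the reference
    strain's LH2A alpha).  *reference_cds_by_id* maps reference ids to coding
    sequences for frameshift detection; when the alpha's best reference has
    no CDS only the premature-stop check applies.
    """
    alpha = operon.alpha
    pseudo = False
    evidence = PseudogeneEvidence()
    ref_cds = None
    if reference_cds_by_id:
        ref_cds = reference_cds_by_id.get(alpha.best_ref_id)
    if ref_cds:
        pseudo, evidence = detect_pseudogene(alpha.cds, ref_cds)
    peptide = alpha.peptide
    if pseudo:
        # conceptual translation up to the first disruption still carries
        # the signature when the lesion is downstream of it
        peptide = _conceptual_peptide(alpha.cds, ref_cds)
    try:
        profile = number_positions(peptide, reference_alpha)
        lh_type = classify_alpha(profile)
    except (NumberingError, ValueError):
        profile = SignatureProfile(GAP, GAP, GAP)
        lh_type = "unclassified"
    subtype, sub_ident, tie = "none", 0.0, False
    if lh_type == "LH2":
        subtype, sub_ident, tie = assign_lh2_subtype(peptide, subtype_references)
    call = LHCall(lh_type, subtype, profile, pseudo, evidence, sub_ident, tie)
    return OperonCall(operon, call, categorize_beta(operon, call))


def _conceptual_peptide(cds: str, reference_cds: str | None) -> str:
    """Best-effort translation of a pseudogene for signature reading.

    Projects the coding sequence onto the reference frame through the
    nucleotide alignment so that a small indel does not scramble everything
    downstream of it.
    """
    if reference_cds is None:
        return translate_cds(cds[: len(cds) - len(cds) % 3])
    alignment = align.align_pair(reference_cds, cds, "nucleotide")
    ref_row, cds_row = alignment[0], alignment[1]
    projected = []
    for r, c in zip(ref_row, cds_row):
        if r == GAP:
            continue  # insertion in the query: drop to restore frame
        projected.append(c if c != GAP else "N")
    projected_cds = "".join(projected)
    from Bio.Seq import Seq

    peptide = str(
        Seq(projected_cds[: len(projected_cds) - len(projected_cds) % 3]).translate(table=11)
    )
    return peptide.rstrip("*").replace("*", "X")


@dataclass
class InventoryRow:
    """One strain's LH gene inventory (the per-strain summary table row)."""

    strain: str
    pucb_count: int
    intact: dict
    pseudo: dict
    lone_alphas: int = 0

    def cell(self, category: str) -> str:
        n_intact = self.intact.get(category, 0)
        n_pseudo = self.pseudo.get(category, 0)
        if n_pseudo == 0:
            return str(n_intact)
        if n_intact == 0 and n_pseudo == 1:
            return "Pseudo"
        return f"{n_intact}+{n_pseudo}Pseudo"


def build_inventory(calls_by_strain: Mapping[str, Sequence[OperonCall]]) -> list[InventoryRow]:
    """Compile per-strain LH gene counts (inventory-table rows).

    Pseudogenes are annotated per category and excluded from intact counts;
    the pucB count is the number of beta-bearing operons.
    """
    rows = []
    for strain, calls in calls_by_strain.items():
        intact = {c: 0 for c in INVENTORY_CATEGORIES}
        pseudo = {c: 0 for c in INVENTORY_CATEGORIES}
        pucb = 0
        lone = 0
        for oc in calls:
            if oc.operon.beta is not None:
                pucb += 1
            else:
                lone += 1
            cat = oc.category
            if cat not in INVENTORY_CATEGORIES:
                continue
            if oc.call.pseudogene:
                pseudo[cat] += 1
            else:
                intact[cat] += 1
        rows.append(InventoryRow(strain, pucb, intact, pseudo, lone))
    return rows


def inventory_to_frame(rows: Sequence[InventoryRow]) -> pd.DataFrame:
    """Inventory rows as a DataFrame with formatted per-category cells."""
    data = []
    for row in rows:
        rec = {"strain": row.strain, "pucB_genes": row.pucb_count}
        for cat in INVENTORY_CATEGORIES:
            rec[cat] = row.cell(cat)
        rec["lone_pucA"] = row.lone_alphas
        data.append(rec)
    return pd.DataFrame(data)


def calls_to_frame(calls: Sequence[OperonCall]) -> pd.DataFrame:
    """Per-gene classification table (one row per operon)."""
    rows = []
    for oc in calls:
        sig = oc.call.signature or SignatureProfile(GAP, GAP, GAP)
        rows.append(dict(
            operon_id=oc.operon.id,
            alpha_gene=oc.operon.alpha.gene_id,
            beta_gene=oc.operon.beta.gene_id if oc.operon.beta else "",
            lh_type=oc.call.lh_type,
            lh2_subtype=oc.call.lh2_subtype,
            beta_category=oc.beta_category or "",
            residue_26=sig.residue_26,
            residue_44=sig.residue_44,
            residue_45=sig.residue_45,
            pseudogene=oc.call.pseudogene,
            pseudogene_evidence=f"{oc.call.evidence.kind}={oc.call.evidence.value}"
            if oc.call.evidence.kind != "none" else "",
            subtype_identity=round(oc.call.subtype_identity, 4),
            tie_flag=oc.call.tie_flag,
        ))
    return pd.DataFrame(rows)
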