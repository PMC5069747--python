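"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere in the package; all
external files (GFF3) use the standard 1-based inclusive convention.  FASTA
is read through Biopython and upcased; writes wrap sequence lines at 70
characters.  Ambiguity codes (N, X, ...) are preserved on read — downstream
distance computation removes ambiguous positions per sequence pair.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


_NUC_CHARS = set("ACGTUNRYSWKMBDHV-")
_PROT_ONLY = set("EFILPQZ*X") - _NUC_CHARS


def guess_alphabet(sequence: str) -> str:
    """Classify a sequence string as 'nucleotide' or 'protein'.

    Any residue that can only occur in a peptide forces 'protein'; otherwise
    sequences composed of IUPAC nucleotide codes are 'nucleotide'.
    """
    upper = sequence.upper()
    if set(upper) - _NUC_CHARS:
        return "protein"
    return "nucleotide"


@dataclass
class SeqRecord:
    """A named sequence with an explicit alphabet flag."""

    id: str
    description: str
    sequence: str
    alphabet: str = "nucleotide"  # 'nucleotide' | 'protein'

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if not self.sequence:
            raise ValueError(f"SeqRecord {self.id!r}: sequence must be non-empty")
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if self.alphabet == "nucleotide" and guess_alphabet(self.sequence) == "protein":
            raise ValueError(
                f"SeqRecord {self.id!r}: flagged nucleotide but contains protein-only letters"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SeqRecord":
        if self.alphabet != "nucleotide":
            raise TypeError("reverse_complement requires a nucleotide record")
        return SeqRecord(
            self.id,
            self.description,
            str(Seq(self.sequence).reverse_complement()),
            "nucleotide",
        )


@dataclass
class GeneFeature:
    """A located genomic feature (internal 0-based half-open coordinates)."""

    contig_id: str
    start: int
    end: int
    strand: str
    feature_type: str = "CDS"
    attributes: dict = field(default_factory=dict)
    source: str = "puctools"
    score: str = "."
    phase: str = "."

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def external_to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """Convert 1-based inclusive coordinates to 0-based half-open."""
    return start_1based - 1, end_inclusive


def internal_to_external(start: int, end: int) -> tuple[int, int]:
    """Convert 0-based half-open coordinates to 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, alphabet: str | None = None) -> list[SeqRecord]:
    """Read a FASTA file into a list of SeqRecord, upcasing sequences.

    Parameters
    ----------
    path : str or Path
        FASTA file; may be empty (returns an empty list).
    alphabet : optional
        Force 'nucleotide' or 'protein'; guessed per record when omitted.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first_bad = next(
            i for i, line in enumerate(text.splitlines(), 1) if line.strip()
        )
        raise FormatError(f"{path}: line {first_bad}: expected FASTA header '>'")
    records = []
    with path.open() as fh:
        for idx, rec in enumerate(SeqIO.parse(fh, "fasta"), 1):
            seq = re.sub(r"\s", "", str(rec.seq)).upper()
            if not seq:
                raise FormatError(f"{path}: record {idx} ({rec.id!r}): empty sequence")
            ab = alphabet or guess_alphabet(seq)
            records.append(SeqRecord(rec.id, rec.description, seq, ab))
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    """Write SeqRecords to FASTA, wrapping sequence lines at 70 characters."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=_desc_tail(r))
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(bio)


def _desc_tail(rec: SeqRecord) -> str:
    # Biopython prints "id description"; avoid doubling the id.
    if rec.description.startswith(rec.id):
        return rec.description[len(rec.id):].strip()
    return rec.description


# ---------------------------------------------------------------------------
# GFF3


def _parse_attributes(text: str) -> dict:
    attrs = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            key, value = part.split("=", 1)
            attrs[key.strip()] = value.strip()
    return attrs


def _format_attributes(attrs: dict) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_gff3(path) -> list[GeneFeature]:
    """Parse a GFF3 file into GeneFeatures with internal coordinates."""
    features = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns, got {len(cols)}")
            contig, source, ftype, start_s, end_s, score, strand, phase, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise FormatError(f"{path}: line {lineno}: end {end1} < start {start1}")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}: line {lineno}: strand must be + or -")
            start, end = external_to_internal(start1, end1)
            features.append(
                GeneFeature(
                    contig_id=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    feature_type=ftype,
                    attributes=_parse_attributes(attr_s),
                    source=source,
                    score=score,
                    phase=phase,
                )
            )
    return features


def write_gff3(features: Iterable[GeneFeature], path, header: str | None = None) -> None:
    """Write GeneFeatures as GFF3 (coordinates converted back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for f in features:
            start1, end1 = internal_to_external(f.start, f.end)
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        f.source,
                        f.feature_type,
                        str(start1),
                        str(end1),
                        f.score,
                        f.strand,
                        f.phase,
                        _format_attributes(f.attributes),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Count tables


LIBRARY_SIZE_ROW = "__library_size__"


def read_count_table(path, libsize_path=None) -> tuple[pd.DataFrame, pd.Series]:
    """Read a gene x sample TSV of nonnegative integer counts.

    Library sizes (uniquely mapped reads per sample) come either from a row
    named ``__library_size__`` inside the table or from a two-column sidecar
    TSV (sample, size) given as *libsize_path*.

    Returns
    -------
    (counts, library_sizes)
        counts: DataFrame indexed by gene id, columns sample ids.
        library_sizes: Series indexed by sample id.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated gene id(s): {', '.join(map(str, dups))}")
    libsizes = None
    if LIBRARY_SIZE_ROW in df.index:
        libsizes = df.loc[LIBRARY_SIZE_ROW].astype(float)
        df = df.drop(index=LIBRARY_SIZE_ROW)
    if libsize_path is not None:
        side = pd.read_csv(libsize_path, sep="\t", index_col=0).iloc[:, 0]
        libsizes = side.astype(float)
    if libsizes is None:
        raise FormatError(
            f"{path}: no library sizes (need a {LIBRARY_SIZE_ROW!r} row or a sidecar file)"
        )
    missing = [s for s in df.columns if s not in libsizes.index]
    if missing:
        raise FormatError(f"{path}: missing library-size entry for sample(s): {missing}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric counts")
    if (values < 0).any():
        raise FormatError(f"{path}: negative counts")
    if not np.allclose(values, np.round(values)):
        raise FormatError(f"{path}: non-integer counts")
    counts = df.astype(np.int64)
    return counts, libsizes.loc[counts.columns]


def write_count_table(counts: pd.DataFrame, libsizes: pd.Series, path) -> None:
    """Write counts with an embedded ``__library_size__`` row."""
    out = counts.copy()
    out.loc[LIBRARY_SIZE_ROW] = libsizes.loc[out.columns].astype(np.int64)
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Spectra (two-column TSV) and Newick


def read_spectrum_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (wavelength nm, absorbance) TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["wavelength_nm", "absorbance"])
    wl = df["wavelength_nm"].to_numpy(float)
    ab = df["absorbance"].to_numpy(float)
    if np.any(np.diff(wl) <= 0):
        raise FormatError(f"{path}: wavelengths must be strictly increasing")
    return wl, ab


def write_spectrum_tsv(wavelengths, absorbance, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for w, a in zip(wavelengths, absorbance):
            fh.write(f"{w:g}\t{a:.6g}\n")


def write_newick(tree, path=None) -> str:
    """Serialize an unrooted tree (phylo.Tree) to Newick.

    Branch lengths are written with 10 significant digits; internal node
    labels carry bootstrap support percentages when present.
    """
    text = tree.to_newick() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
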