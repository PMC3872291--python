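"""Exon architecture and splice-variant catalog for the MYBPC1 gene.

The slow isoform of myosin binding protein-C (sMyBP-C) is produced from the
single MYBPC1 gene as a family of splice variants that differ by short
in-frame segments in the Pro/Ala-rich NH2-terminus (exons 2-5), the M-motif
(exon 10), FnIII domain C7 (exon 23), and the extreme COOH-terminus
(exons 31-33).  This module holds the machine-readable exon architecture,
the per-variant inclusion patterns, and the splice grammar that constrains
them:

* cassette exons preserve the reading frame (nucleotide length = 3 x residue
  length);
* exon 33 carries coding sequence only when exon 32 is spliced out, because
  exon 32 otherwise supplies the stop codon;
* one human variant (h-v012) arises from an internal translation start in
  exon 7 rather than from exon skipping, and is modelled with a
  ``tss_truncation`` marker so it does not inflate cassette-splicing counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "ExonSpec",
    "InclusionPattern",
    "VariantRecord",
    "TailSpec",
    "ValidationReport",
    "CatalogError",
    "SchemaError",
    "CASSETTE_EXONS",
    "ALTERNATIVE_ELEMENTS",
    "load_architecture",
    "load_catalog",
    "write_catalog",
    "resolve_tail",
    "validate_pattern",
    "nterm_combination_set",
    "alternative_exons",
    "get_variant",
]

#: Cassette exons with printed residue counts (in-frame, included/excluded as units).
CASSETTE_EXONS = (2, 3, 4, 5, 10, 23)

#: All alternatively used elements, including the terminal exons 31/32 and the
#: coding/UTR toggle of exon 33.
ALTERNATIVE_ELEMENTS = (2, 3, 4, 5, 10, 23, 31, 32, 33)


class CatalogError(ValueError):
    """Raised for catalog-level problems (duplicate ids, invalid patterns)."""


class SchemaError(CatalogError):
    """Raised when a catalog file does not conform to the expected schema."""


@dataclass(frozen=True)
class ExonSpec:
    """One exon of the 33-exon MYBPC1 transcript (1-based numbering)."""

    index: int
    nt_length: Optional[int]
    aa_length: Optional[int]
    region: str
    splice_class: str  # constitutive | cassette | alternate_terminal

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 33:
            raise ValueError(f"exon index {self.index} outside 1-33")


@dataclass(frozen=True)
class InclusionPattern:
    """In/out decisions for the alternatively spliced elements of one variant.

    ``exon33_coding`` is True when exon 33 contributes coding sequence (only
    possible when exon 32 is spliced out and exon 33 supplies the stop codon).
    ``tss_truncation`` names the exon holding an internal translation start;
    elements upstream of it are not part of the protein and are excluded from
    splice statistics.
    """

    exon2: bool
    exon3: bool
    exon4: bool
    exon5: bool
    exon10: bool
    exon23: bool
    exon31: bool
    exon32: bool
    exon33_coding: bool
    tss_truncation: Optional[int] = None

    def flag(self, exon: int) -> bool:
        if exon == 33:
            return self.exon33_coding
        return getattr(self, f"exon{exon}")

    @property
    def nterm(self) -> tuple[bool, bool, bool, bool]:
        """The (exon2, exon3, exon4, exon5) Pro/Ala-region tuple."""
        return (self.exon2, self.exon3, self.exon4, self.exon5)

    @property
    def truncated(self) -> bool:
        return self.tss_truncation is not None

    def masked(self, exon: int) -> bool:
        """True when the exon lies upstream of an internal translation start."""
        return self.truncated and exon < self.tss_truncation


@dataclass(frozen=True)
class VariantRecord:
    """One cataloged sMyBP-C variant with its printed molecular weight."""

    id: str
    species: str  # human | mouse
    pattern: InclusionPattern
    printed_mw: float  # kDa, as printed
    accession: str
    partial: bool = False


@dataclass(frozen=True)
class TailSpec:
    """Residues following Ig domain C10 for one (exon31, exon32) state."""

    aa_after_C10: int
    stop_exon: int
    contributing_exons: tuple[int, ...]


# The four legal COOH-terminal states.  With both terminal exons retained,
# exon 31 encodes 19 residues and exon 32 another 7 plus the stop codon; with
# exon 31 alone, exon 33 supplies 16 further residues and the stop; exon 32
# alone encodes just 3 residues before its stop; with both spliced out,
# exon 33 encodes a 33-residue tail and the stop.
_TAILS = {
    (True, True): TailSpec(19 + 7, 32, (31, 32)),
    (True, False): TailSpec(19 + 16, 33, (31, 33)),
    (False, True): TailSpec(3, 32, (32,)),
    (False, False): TailSpec(33, 33, (33,)),
}


def resolve_tail(pattern: InclusionPattern) -> TailSpec:
    """Return the post-C10 tail implied by the (exon31, exon32) state.

    Total over the four states; the image has exactly four distinct tails
    (26, 35, 3 and 33 residues).
    """
    return _TAILS[(pattern.exon31, pattern.exon32)]


@dataclass(frozen=True)
class ValidationReport:
    valid: bool
    violations: tuple[str, ...] = ()


def load_architecture(path: Optional[Path | str] = None) -> list[ExonSpec]:
    """Load the exon architecture (packaged JSON by default)."""
    if path is None:
        text = resources.files("smybpc.data").joinpath("exon_architecture.json").read_text()
    else:
        text = Path(path).read_text()
    entries = json.loads(text)
    specs = [ExonSpec(**e) for e in entries]
    indices = [s.index for s in specs]
    if len(set(indices)) != len(indices):
        raise SchemaError("duplicate exon indices in architecture")
    return specs


def validate_pattern(
    pattern: InclusionPattern,
    architecture: Optional[Sequence[ExonSpec]] = None,
) -> ValidationReport:
    """Check a pattern against the splice grammar.

    Never raises on content; returns an itemized report.  A pattern passes
    when every cassette exon of the architecture is frame-preserving, the
    exon 32 / exon 33 stop-codon rule holds, and any internal translation
    start is legal (names an exon in range with all upstream cassettes
    marked absent).
    """
    if architecture is None:
        architecture = load_architecture()
    violations: list[str] = []
    for spec in architecture:
        if spec.splice_class == "cassette" and spec.nt_length is not None:
            if spec.nt_length != 3 * (spec.aa_length or 0):
                violations.append(
                    f"exon {spec.index}: nt_length {spec.nt_length} != 3 x aa_length"
                )
    if pattern.exon33_coding != (not pattern.exon32):
        violations.append(
            "exon 33 carries coding sequence iff exon 32 is spliced out "
            f"(exon32={'present' if pattern.exon32 else 'absent'}, "
            f"exon33_coding={pattern.exon33_coding})"
        )
    if pattern.truncated:
        tss = pattern.tss_truncation
        if not 2 <= tss <= 33:
            violations.append(f"tss_truncation {tss} outside exons 2-33")
        else:
            for exon in CASSETTE_EXONS:
                if exon < tss and pattern.flag(exon):
                    violations.append(
                        f"exon {exon} marked present but lies upstream of the "
                        f"internal start in exon {tss}"
                    )
    return ValidationReport(valid=not violations, violations=tuple(violations))


_FLAG_COLUMNS = (
    "exon2", "exon3", "exon4", "exon5",
    "exon10", "exon23", "exon31", "exon32", "exon33_coding",
)
_COLUMNS = (
    "id", "species", *_FLAG_COLUMNS,
    "tss_truncation", "printed_mw_kda", "accession", "partial",
)


def _parse_flag(value: str, row_id: str, column: str) -> bool:
    value = str(value).strip()
    if value in {"+", "present", "coding"}:
        return True
    if value in {"-", "−", "absent", "utr_only", "3'UTR"}:
        return False
    raise SchemaError(f"row {row_id!r}, column {column!r}: bad flag {value!r}")


def load_catalog(path: Optional[Path | str] = None) -> list[VariantRecord]:
    """Load a variant catalog TSV (the packaged Table-1 catalog by default).

    Every row is schema-checked and its pattern validated against the splice
    grammar; duplicate ids or grammar violations raise :class:`CatalogError`.
    """
    if path is None:
        with resources.as_file(
            resources.files("smybpc.data").joinpath("catalog.tsv")
        ) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"catalog missing columns: {missing}")
    architecture = load_architecture()
    records: list[VariantRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        rid = str(row["id"]).strip()
        if rid in seen:
            raise CatalogError(f"duplicate variant id {rid!r}")
        seen.add(rid)
        species = str(row["species"]).strip()
        if species not in {"human", "mouse"}:
            raise SchemaError(f"row {rid!r}, column 'species': bad value {species!r}")
        flags = {c: _parse_flag(row[c], rid, c) for c in _FLAG_COLUMNS}
        tss_raw = row["tss_truncation"]
        tss = None if pd.isna(tss_raw) or str(tss_raw).strip() == "" else int(float(tss_raw))
        try:
            mw = float(row["printed_mw_kda"])
        except (TypeError, ValueError) as exc:
            raise SchemaError(
                f"row {rid!r}, column 'printed_mw_kda': bad value {row['printed_mw_kda']!r}"
            ) from exc
        pattern = InclusionPattern(tss_truncation=tss, **flags)
        report = validate_pattern(pattern, architecture)
        if not report.valid:
            raise CatalogError(f"row {rid!r}: {'; '.join(report.violations)}")
        records.append(
            VariantRecord(
                id=rid,
                species=species,
                pattern=pattern,
                printed_mw=mw,
                accession=str(row["accession"]).strip(),
                partial=_parse_flag(row["partial"], rid, "partial"),
            )
        )
    return records


def write_catalog(records: Iterable[VariantRecord], path: Path | str) -> None:
    """Write records as a catalog TSV that round-trips through load_catalog."""
    rows = []
    for rec in records:
        flag_cells = {
            c: "+" if getattr(rec.pattern, c) else "-" for c in _FLAG_COLUMNS
        }
        row = {
            "id": rec.id,
            "species": rec.species,
            **flag_cells,
            "tss_truncation": "" if rec.pattern.tss_truncation is None else str(rec.pattern.tss_truncation),
            "printed_mw_kda": f"{rec.printed_mw:g}",
            "accession": rec.accession,
            "partial": "+" if rec.partial else "-",
        }
        rows.append(row)
    pd.DataFrame(rows, columns=list(_COLUMNS)).to_csv(path, sep="\t", index=False)


def _countable(records: Iterable[VariantRecord], species: str = "human") -> list[VariantRecord]:
    return [r for r in records if r.species == species and not r.partial]


def nterm_combination_set(catalog: Iterable[VariantRecord]) -> set[tuple[bool, bool, bool, bool]]:
    """Distinct NH2-terminal (exon2..exon5) tuples among human full-length
    variants that possess a Pro/Ala region (internal-start variants excluded).
    """
    return {
        r.pattern.nterm
        for r in _countable(catalog)
        if not r.pattern.truncated
    }


def alternative_exons(catalog: Iterable[VariantRecord]) -> set[int]:
    """Exon indices whose coding status varies across human full-length
    variants.

    Exon 33's coding/UTR toggle counts as variation; exons masked by an
    internal translation start are excluded from the comparison for that
    variant.
    """
    varying: set[int] = set()
    records = _countable(catalog)
    for exon in ALTERNATIVE_ELEMENTS:
        values = {
            r.pattern.flag(exon)
            for r in records
            if not r.pattern.masked(exon)
        }
        if len(values) > 1:
            varying.add(exon)
    return varying


def get_variant(catalog: Iterable[VariantRecord], variant_id: str) -> VariantRecord:
    """Fetch a record by id, raising :class:`CatalogError` if absent."""
    for rec in catalog:
        if rec.id == variant_id:
            return rec
    raise CatalogError(f"variant {variant_id!r} not in catalog")
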