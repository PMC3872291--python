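"""Rule-based proteoform annotation of sMyBP-C variants.

Three categorical annotations follow directly from a variant's exon
composition:

* **Phosphorylation-site complement.**  The NH2-terminus is phosphorylated by
  PKA and PKC at up to five sites.  Two Pro/Ala-region sites are constitutive
  (human T64/S85, mouse S62/S83 plus the mouse-only T84); human S61 / mouse
  S59 sits in the alternatively spliced segment encoded by exon 5; and human
  S206 / mouse S204 in the M-motif is encoded by exon 10.  Kinase-assay
  confirmation exists only for mouse, so sites are reported as *predicted*.

* **Sarcomeric localization.**  The COOH-terminus targets the protein:
  variants retaining exons 31 and 32 concentrate at the M-band periphery,
  variants lacking exon 31 but keeping exon 32 occupy the C-zone of the
  A-band, and the two unique tails (exon 31 only; neither exon) have unknown
  localization.

* **Actomyosin / LMM interaction class.**  NH2-terminal composition sets the
  regulatory potency on cross-bridge formation, and the COOH-terminus sets
  light-meromyosin binding.  These are categorical labels, not affinities.
"""

from __future__ import annotations

from dataclasses import dataclass
from .catalog import VariantRecord

__all__ = [
    "PhosphoSite",
    "PhosphoAnnotation",
    "LocalizationCall",
    "InteractionProfile",
    "AnnotationError",
    "HUMAN_SITES",
    "MOUSE_SITES",
    "annotate_phospho",
    "predict_localization",
    "interaction_profile",
]


class AnnotationError(ValueError):
    """Raised when a variant cannot be annotated (e.g. partial records)."""


@dataclass(frozen=True)
class PhosphoSite:
    """A named phosphorylation site with its kinase and region."""

    name: str
    kinase: str  # PKA | PKC | PKA+PKC
    region: str  # ProAla | M-motif
    mouse_only: bool = False


# Human numbering with the homologous mouse site noted in the name map below.
H_S61 = PhosphoSite("S61", "PKA", "ProAla")
H_T64 = PhosphoSite("T64", "PKA", "ProAla")
H_S85 = PhosphoSite("S85", "PKC", "ProAla")
H_S206 = PhosphoSite("S206", "PKA+PKC", "M-motif")

M_S59 = PhosphoSite("S59", "PKA", "ProAla")
M_S62 = PhosphoSite("S62", "PKA", "ProAla")
M_S83 = PhosphoSite("S83", "PKC", "ProAla")
M_T84 = PhosphoSite("T84", "PKC", "ProAla", mouse_only=True)
M_S204 = PhosphoSite("S204", "PKA+PKC", "M-motif")

HUMAN_SITES = (H_S61, H_T64, H_S85, H_S206)
MOUSE_SITES = (M_S59, M_S62, M_S83, M_T84, M_S204)

#: Human site -> homologous mouse site (T84 has no human counterpart).
HOMOLOG_MAP = {"S61": "S59", "T64": "S62", "S85": "S83", "S206": "S204"}


@dataclass(frozen=True)
class PhosphoAnnotation:
    """Predicted phosphorylation-site complement of one variant."""

    variant_id: str
    sites: tuple[PhosphoSite, ...]
    predicted: bool
    notes: tuple[str, ...] = ()

    @property
    def site_names(self) -> frozenset[str]:
        return frozenset(s.name for s in self.sites)


def annotate_phospho(variant: VariantRecord) -> PhosphoAnnotation:
    """Predict the phosphorylation sites carried by a full-length variant.

    Pro/Ala sites require the Pro/Ala region (absent in internal-start
    variants); the exon-5 site additionally requires exon 5, and the M-motif
    site requires exon 10.  Partial records are refused because their exon
    composition is incomplete.
    """
    if variant.partial:
        raise AnnotationError(
            f"{variant.id}: partial variant; full-length exon composition "
            "unknown, refusing phospho annotation"
        )
    pattern = variant.pattern
    has_proala = not pattern.truncated
    notes: list[str] = []
    sites: list[PhosphoSite] = []
    if variant.species == "human":
        if has_proala:
            if pattern.exon5:
                sites.append(H_S61)
            sites.extend([H_T64, H_S85])
        if pattern.exon10:
            sites.append(H_S206)
        notes.append(
            "human sites inferred by homology to assayed mouse sites; "
            "phosphorylation is predicted, not measured"
        )
    else:
        if has_proala:
            if pattern.exon5:
                sites.append(M_S59)
            sites.extend([M_S62, M_S83, M_T84])
        if pattern.exon10:
            sites.append(M_S204)
    if pattern.truncated:
        notes.append(
            "internal translation start removes the Pro/Ala region; note the "
            "'four Pro/Ala sites' phrasing in the source literature follows "
            "mouse numbering (the human region carries three)"
        )
    return PhosphoAnnotation(
        variant_id=variant.id,
        sites=tuple(sites),
        predicted=variant.species == "human",
        notes=tuple(notes),
    )


@dataclass(frozen=True)
class LocalizationCall:
    value: str  # A-band | M-band | unknown


def predict_localization(variant: VariantRecord) -> LocalizationCall:
    """Map the (exon31, exon32) tail state to a sarcomeric compartment.

    Both retained -> M-band periphery; exon 32 only -> A-band C-zone; the two
    unique tails -> unknown (never imputed).
    """
    p = variant.pattern
    if p.exon31 and p.exon32:
        return LocalizationCall("M-band")
    if not p.exon31 and p.exon32:
        return LocalizationCall("A-band")
    return LocalizationCall("unknown")


@dataclass(frozen=True)
class InteractionProfile:
    nterm_class: str  # strong_actin_myosin | strong_competing | moderate_hmm_only | unknown
    lmm_binding: str  # preferential | weak | unknown


def interaction_profile(variant: VariantRecord) -> InteractionProfile:
    """Classify NH2-terminal actomyosin regulation and COOH-terminal LMM binding.

    Variants with all of exons 2-5 interact with both actin and myosin
    (strongest regulators); exon 2+3 variants compete with actin for the
    myosin head; the exon-2-only NH2-terminus binds HMM only (moderate); the
    remaining unique NH2-termini are uncharacterized.  LMM binding follows
    the tail: both terminal exons -> preferential, exon 32 only -> weak,
    unique tails -> unknown.
    """
    p = variant.pattern
    if p.truncated:
        nterm = "unknown"
    elif p.exon2 and p.exon3 and p.exon4 and p.exon5:
        nterm = "strong_actin_myosin"
    elif p.exon2 and p.exon3 and not p.exon4 and not p.exon5:
        nterm = "strong_competing"
    elif p.nterm == (True, False, False, False):
        nterm = "moderate_hmm_only"
    else:
        nterm = "unknown"
    if p.exon31 and p.exon32:
        lmm = "preferential"
    elif not p.exon31 and p.exon32:
        lmm = "weak"
    else:
        lmm = "unknown"
    return InteractionProfile(nterm_class=nterm, lmm_binding=lmm)
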