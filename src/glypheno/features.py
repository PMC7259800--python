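"""Multiparametric mutation scoring (MMS) for GLDC missense variants.

Each missense mutation is scored on 18 binary parameters drawn from four
broad categories: predicted stability effect (destabilizing / stabilizing
ΔΔG), evolutionary conservation (of the residue and of the substitution),
location (secondary structure, C-terminus, active site and its 7 Å shell,
N-terminal PLP pocket, H-protein interface, dimerization interface) and
change in amino-acid properties (polarity, charge, aromaticity, proline,
codon availability, volume).  Every parameter carries unit weight +1 except
conservation-of-substitution, which scores −1 because a substitution that is
well tolerated through evolution argues against pathogenicity.

Compound-heterozygous genotypes are scored by averaging: a parameter met by
both alleles contributes 1, by one allele 0.5.  Four additional indicator
parameters (deletion, nonsense/frameshift, intronic/splice, mitochondrial
leader) absorb non-missense alleles, each contributing 0.5 per matching
allele.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import ContractError, ValidationError

#: The 18 missense parameters, in the order of the trained-weight table.
MISSENSE_PARAMETERS = [
    "stabilizing",
    "destabilizing",
    "cons_residue",
    "cons_substitution",
    "helix",
    "sheet",
    "c_term",
    "active_site",
    "active_region",
    "nterm_plp",
    "h_interface",
    "dimer_interface",
    "d_polarity",
    "d_charge",
    "d_aromaticity",
    "d_proline",
    "d_codon",
    "d_size",
]

#: Indicator parameters for non-missense alleles of compound heterozygotes.
NON_MISSENSE_PARAMETERS = ["deletion", "nonsense", "intronic", "mito_leader"]

ALL_PARAMETERS = MISSENSE_PARAMETERS + NON_MISSENSE_PARAMETERS

ALLELE_CLASSES = [
    "missense",
    "deletion",
    "nonsense_frameshift",
    "intronic_splice",
    "mito_leader",
]

#: Map from allele class to the indicator parameter it triggers.
_CLASS_TO_PARAMETER = {
    "deletion": "deletion",
    "nonsense_frameshift": "nonsense",
    "intronic_splice": "intronic",
    "mito_leader": "mito_leader",
}

SEC_STRUCTS = ("helix", "sheet", "loop")

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def unit_signs() -> pd.Series:
    """Fixed unit-weight vector: +1 everywhere except cons_substitution = -1."""
    s = pd.Series(1.0, index=ALL_PARAMETERS)
    s["cons_substitution"] = -1.0
    return s


def _load_property_tables() -> dict:
    with resources.files("glypheno.data").joinpath("property_tables.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class PropertyTables:
    """Amino-acid property classes used by the Δ-property parameters.

    Polarity and charge classes, the aromatic set, standard-genetic-code
    codon counts, and residue volumes (Zamyatnin scale, Å³).
    """

    polar: frozenset
    nonpolar: frozenset
    positive: frozenset
    negative: frozenset
    aromatic: frozenset
    codon_counts: dict
    volume_a3: dict

    @classmethod
    def default(cls) -> "PropertyTables":
        raw = _load_property_tables()
        return cls(
            polar=frozenset(raw["polarity"]["polar"]),
            nonpolar=frozenset(raw["polarity"]["nonpolar"]),
            positive=frozenset(raw["charge"]["positive"]),
            negative=frozenset(raw["charge"]["negative"]),
            aromatic=frozenset(raw["aromatic"]),
            codon_counts=dict(raw["codon_counts"]),
            volume_a3=dict(raw["volume_a3"]),
        )

    def charge_class(self, aa: str) -> str:
        if aa in self.positive:
            return "positive"
        if aa in self.negative:
            return "negative"
        return "neutral"

    def polarity_class(self, aa: str) -> str:
        return "polar" if aa in self.polar else "nonpolar"


_DEFAULT_TABLES = None


def default_property_tables() -> PropertyTables:
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = PropertyTables.default()
    return _DEFAULT_TABLES


@dataclass
class FeatureConfig:
    """Thresholds controlling the 18 parameters.

    destabilizing_ddg:
        ΔΔG (kcal/mol) below which a substitution counts as destabilizing.
    stabilizing_ddg:
        ΔΔG at or above which it counts as (rigidifying) stabilizing.
    conserved_grade:
        Consurf-style grade (1..9) at or above which the residue counts as
        highly conserved.
    conserved_blosum:
        BLOSUM62 score at or above which the substitution counts as
        evolutionarily tolerated (scores the −1 parameter).
    c_term_start:
        First position of the C-terminal span.
    codon_delta:
        Minimum |codons(ref) − codons(alt)| for the codon-availability flag.
    volume_delta_a3:
        Minimum |volume change| (Å³) for the size flag.
    """

    destabilizing_ddg: float = -1.5
    stabilizing_ddg: float = 1.5
    conserved_grade: int = 7
    conserved_blosum: int = 0
    c_term_start: int = 506
    codon_delta: int = 4
    volume_delta_a3: float = 50.0
    protein_length: int = 1020
    tables: PropertyTables = field(default_factory=default_property_tables)


@dataclass
class MutationAnnotation:
    """Structural / conservation / biophysical facts about one missense variant."""

    mutation: str
    position: int
    ref_aa: str
    alt_aa: str
    ddg_kcal_mol: float
    conservation_grade: int
    blosum62: int
    sec_struct: str
    active_site: bool = False
    active_region_7A: bool = False
    nterm_plp: bool = False
    h_interface: bool = False
    dimer_interface: bool = False

    def __post_init__(self):
        if self.ref_aa not in STANDARD_AA or self.alt_aa not in STANDARD_AA:
            raise ValidationError(
                f"{self.mutation}: unknown amino acid letter "
                f"({self.ref_aa!r} -> {self.alt_aa!r})"
            )
        if self.ref_aa == self.alt_aa:
            raise ValidationError(f"{self.mutation}: ref and alt amino acids are equal")
        if self.position < 1:
            raise ValidationError(f"{self.mutation}: position must be >= 1")
        if not 1 <= int(self.conservation_grade) <= 9:
            raise ValidationError(
                f"{self.mutation}: conservation grade {self.conservation_grade} not in 1..9"
            )
        if self.sec_struct not in SEC_STRUCTS:
            raise ValidationError(
                f"{self.mutation}: sec_struct {self.sec_struct!r} not in {SEC_STRUCTS}"
            )
        if self.active_site and self.active_region_7A:
            raise ValidationError(
                f"{self.mutation}: active_site and active_region_7A are mutually "
                "exclusive (the 7 Å shell excludes the site itself)"
            )
        if not math.isfinite(float(self.ddg_kcal_mol)):
            raise ValidationError(f"{self.mutation}: ΔΔG must be finite")


@dataclass
class AlleleSpec:
    """One allele of a genotype: its class and, for missense, its annotation."""

    name: str
    allele_class: str
    annotation: MutationAnnotation | None = None

    def __post_init__(self):
        if self.allele_class not in ALLELE_CLASSES:
            raise ValidationError(
                f"allele {self.name!r}: class {self.allele_class!r} "
                f"not in {ALLELE_CLASSES}"
            )
        if self.allele_class == "missense" and self.annotation is None:
            raise ValidationError(f"missense allele {self.name!r} needs an annotation")
        if self.allele_class != "missense" and self.annotation is not None:
            raise ValidationError(
                f"non-missense allele {self.name!r} must not carry an annotation"
            )


STABILITY_CLASSES = (
    "very_destabilizing",
    "destabilizing",
    "negligible",
    "stabilizing",
    "very_stabilizing",
)


def classify_stability(ddg: float) -> str:
    """Bin a predicted ΔΔG (kcal/mol) into the five stability classes.

    Bins: < −5 | [−5, −1.5) | [−1.5, 1.5] | (1.5, 5] | > 5.  The negligible
    band is closed at both ends.
    """
    ddg = float(ddg)
    if not math.isfinite(ddg):
        raise ValidationError(f"ΔΔG must be finite, got {ddg!r}")
    if ddg < -5:
        return "very_destabilizing"
    if ddg < -1.5:
        return "destabilizing"
    if ddg <= 1.5:
        return "negligible"
    if ddg <= 5:
        return "stabilizing"
    return "very_stabilizing"


def derive_parameter_vector(
    ann: MutationAnnotation, cfg: FeatureConfig | None = None
) -> pd.Series:
    """Evaluate the 18 missense parameters for one annotated mutation.

    Returns a {0,1}-valued Series over all 22 parameter keys (the four
    non-missense indicators are 0 for a missense annotation), named after
    the mutation.
    """
    cfg = cfg or FeatureConfig()
    t = cfg.tables
    ref, alt = ann.ref_aa, ann.alt_aa
    v = pd.Series(0.0, index=ALL_PARAMETERS, name=ann.mutation)

    v["destabilizing"] = float(ann.ddg_kcal_mol < cfg.destabilizing_ddg)
    v["stabilizing"] = float(ann.ddg_kcal_mol >= cfg.stabilizing_ddg)
    v["cons_residue"] = float(int(ann.conservation_grade) >= cfg.conserved_grade)
    v["cons_substitution"] = float(int(ann.blosum62) >= cfg.conserved_blosum)
    v["helix"] = float(ann.sec_struct == "helix")
    v["sheet"] = float(ann.sec_struct == "sheet")
    v["c_term"] = float(ann.position >= cfg.c_term_start)
    v["active_site"] = float(ann.active_site)
    v["active_region"] = float(ann.active_region_7A)
    v["nterm_plp"] = float(ann.nterm_plp)
    v["h_interface"] = float(ann.h_interface)
    v["dimer_interface"] = float(ann.dimer_interface)
    v["d_polarity"] = float(t.polarity_class(ref) != t.polarity_class(alt))
    v["d_charge"] = float(t.charge_class(ref) != t.charge_class(alt))
    v["d_aromaticity"] = float((ref in t.aromatic) != (alt in t.aromatic))
    v["d_proline"] = float("P" in (ref, alt))
    v["d_codon"] = float(
        abs(t.codon_counts[ref] - t.codon_counts[alt]) >= cfg.codon_delta
    )
    v["d_size"] = float(
        abs(t.volume_a3[alt] - t.volume_a3[ref]) >= cfg.volume_delta_a3
    )
    return v


def _check_homozygous_form(v: pd.Series):
    if set(v.index) != set(ALL_PARAMETERS):
        raise ContractError("parameter vector has unexpected keys")
    if not v[MISSENSE_PARAMETERS].isin([0.0, 1.0]).all():
        raise ContractError(
            "homozygous-form vector must have {0,1} missense entries "
            "(got a heterozygous composite?)"
        )
    if (v[NON_MISSENSE_PARAMETERS] != 0).any():
        raise ContractError("homozygous-form vector must have zero non-missense entries")


def mms(v: pd.Series) -> float:
    """Signed unit-weight sum of a parameter vector (homozygous or composite)."""
    return float((unit_signs().reindex(v.index) * v).sum())


def mms_homozygous(v: pd.Series) -> float:
    """MMS of a homozygous-form ({0,1}) vector: Σ unit_signs · v, an integer."""
    _check_homozygous_form(v)
    return mms(v)


def allele_vector(allele: AlleleSpec, cfg: FeatureConfig | None = None) -> pd.Series:
    """Full-weight parameter vector of a single allele.

    Missense alleles evaluate the 18 parameters; non-missense alleles set
    their class indicator to 1.
    """
    if allele.allele_class == "missense":
        return derive_parameter_vector(allele.annotation, cfg)
    v = pd.Series(0.0, index=ALL_PARAMETERS, name=allele.name)
    v[_CLASS_TO_PARAMETER[allele.allele_class]] = 1.0
    return v


def combine_heterozygous(
    a1: AlleleSpec, a2: AlleleSpec, cfg: FeatureConfig | None = None
) -> pd.Series:
    """Composite parameter vector of a compound-heterozygous genotype.

    Each parameter contributes 0.5 per allele meeting its condition, so a
    condition met by both alleles scores 1 and by one allele 0.5.  A
    non-missense allele contributes 0 to every missense parameter and 0.5 to
    its class indicator.  At least one allele must be missense.
    """
    if a1.allele_class != "missense" and a2.allele_class != "missense":
        raise ContractError(
            "unsupported genotype: compound-heterozygous scoring requires at "
            "least one missense allele"
        )
    v = 0.5 * (allele_vector(a1, cfg) + allele_vector(a2, cfg))
    v.name = f"{a1.name}/{a2.name}"
    return v


MMS_CLASSES = ("below_scale", "mild", "moderate", "severe")


def classify_mms(score: float) -> str:
    """Mild (1–2), moderate (3–4), severe (≥5); scores below 1 are below-scale."""
    score = float(score)
    if not math.isfinite(score):
        raise ValidationError("MMS must be finite")
    if score < 1:
        return "below_scale"
    if score <= 2:
        return "mild"
    if score < 5:
        return "moderate"
    return "severe"


def annotations_from_frame(df: pd.DataFrame) -> dict:
    """Build MutationAnnotation objects from an annotation table, keyed by name."""
    out = {}
    for row in df.itertuples(index=False):
        out[row.mutation] = MutationAnnotation(
            mutation=row.mutation,
            position=int(row.position),
            ref_aa=row.ref_aa,
            alt_aa=row.alt_aa,
            ddg_kcal_mol=float(row.ddg_kcal_mol),
            conservation_grade=int(row.conservation_grade),
            blosum62=int(row.blosum62),
            sec_struct=row.sec_struct,
            active_site=bool(int(row.active_site)),
            active_region_7A=bool(int(row.active_region_7A)),
            nterm_plp=bool(int(row.nterm_plp)),
            h_interface=bool(int(row.h_interface)),
            dimer_interface=bool(int(row.dimer_interface)),
        )
    return out


_BLOSUM62 = None


def blosum62_score(ref: str, alt: str) -> int:
    """BLOSUM62 substitution score for an ordered amino-acid pair."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return int(_BLOSUM62[ref, alt])
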