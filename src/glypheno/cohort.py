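"""Clinical outcome scoring (COS) for NKH patient records.

Disease severity is scored on four major symptomatic domains — seizures,
cognitive disorders, brain malformation, and muscle/movement control — each
on a Likert-like 0–3 scale.  The seizure scale is the non-linear set {0,1,3}
(controlled vs intractable seizures), and brain malformation is the binary
{0,3} (any structural malformation scores 3).  The clinical outcome score
(COS) is the sum of the scored domains, with a maximum of 12.

A domain reported asymptomatic scores 0; a domain not mentioned in the case
report is *missing* and contributes nothing — the two states are distinct
throughout the package.  Deceased patients are not scored, and records with
fewer than two scored domains are excluded from cohort analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import ValidationError

DOMAINS = ["seizures", "cognitive", "brain_malformation", "muscle_movement"]

LEGAL_DOMAIN_VALUES = {
    "seizures": {0, 1, 3},
    "cognitive": {0, 1, 2, 3},
    "brain_malformation": {0, 3},
    "muscle_movement": {0, 1, 2, 3},
}

MAX_COS = 12

ZYGOSITIES = ("homozygous", "compound_heterozygous")

SEVERITY_CLASSES = ("asymptomatic", "attenuated", "severe")


@dataclass
class PatientRecord:
    """One clinical case: genotype, vital status and four optional domain scores.

    Domain attributes are ``None`` when the case report did not mention the
    domain ("unscored"), which is distinct from an explicit 0 ("scored as
    absent").
    """

    patient_id: str
    zygosity: str
    allele1: str
    allele2: str
    allele1_class: str = "missense"
    allele2_class: str = "missense"
    sex: str = "unknown"
    age_years: float | None = None
    deceased: bool = False
    seizures: int | None = None
    cognitive: int | None = None
    brain_malformation: int | None = None
    muscle_movement: int | None = None

    def __post_init__(self):
        if self.zygosity not in ZYGOSITIES:
            raise ValidationError(
                f"patient {self.patient_id}: zygosity {self.zygosity!r} "
                f"not in {ZYGOSITIES}"
            )
        if self.zygosity == "homozygous" and self.allele1 != self.allele2:
            raise ValidationError(
                f"patient {self.patient_id}: homozygous record with "
                f"allele1 != allele2 ({self.allele1} vs {self.allele2})"
            )
        for d in DOMAINS:
            val = getattr(self, d)
            if val is not None and int(val) not in LEGAL_DOMAIN_VALUES[d]:
                raise ValidationError(
                    f"patient {self.patient_id}: illegal value {val} for "
                    f"domain {d} (legal: {sorted(LEGAL_DOMAIN_VALUES[d])})"
                )

    def domain_scores(self) -> dict:
        return {d: getattr(self, d) for d in DOMAINS}

    def n_scored_domains(self) -> int:
        return sum(getattr(self, d) is not None for d in DOMAINS)


@dataclass
class SymptomVocabulary:
    """Case-insensitive mapping from recorded symptom terms to disease categories."""

    mapping: dict = field(default_factory=dict)

    @classmethod
    def default(cls) -> "SymptomVocabulary":
        path = resources.files("glypheno.data").joinpath("symptom_vocabulary.tsv")
        with path.open() as fh:
            df = pd.read_csv(fh, sep="\t")
        return cls({t.strip().lower(): c for t, c in zip(df["term"], df["category"])})

    def map_symptom(self, term: str) -> str:
        """Exact or case-folded lookup; unknown terms return ``"unclassified"``."""
        return self.mapping.get(str(term).strip().lower(), "unclassified")


def map_symptom_to_domain(term: str, vocabulary: SymptomVocabulary | None = None) -> str:
    """Map a free-text symptom to its disease category, never guessing."""
    vocab = vocabulary or _default_vocabulary()
    return vocab.map_symptom(term)


_VOCAB = None


def _default_vocabulary() -> SymptomVocabulary:
    global _VOCAB
    if _VOCAB is None:
        _VOCAB = SymptomVocabulary.default()
    return _VOCAB


def compute_cos(record: PatientRecord) -> int | None:
    """Sum of the non-missing domain scores; ``None`` if no domain was scored."""
    scores = [s for s in record.domain_scores().values() if s is not None]
    if not scores:
        return None
    return int(sum(int(s) for s in scores))


def filter_cohort(records: list) -> tuple[list, list]:
    """Apply the cohort eligibility rules, in order.

    Deceased records are removed first, then records with fewer than two
    scored domains.  Returns the eligible records (order preserved) and an
    exclusion log of ``(patient_id, reason)`` pairs in exclusion order.
    """
    log = []
    alive = []
    for r in records:
        if r.deceased:
            log.append((r.patient_id, "deceased"))
        else:
            alive.append(r)
    eligible = []
    for r in alive:
        if r.n_scored_domains() < 2:
            log.append((r.patient_id, "fewer than 2 scored domains"))
        else:
            eligible.append(r)
    return eligible, log


def classify_severity(cos: int, attenuated_max: int = 5) -> str:
    """Asymptomatic (COS 0), attenuated (1..attenuated_max) or severe (above).

    The default boundary follows the three-class gating used for the
    allele-vs-allele display: attenuated is COS 1–5 and severe is COS > 5.
    """
    cos = int(cos)
    if not 0 <= cos <= MAX_COS:
        raise ValidationError(f"COS {cos} out of range 0..{MAX_COS}")
    if cos == 0:
        return "asymptomatic"
    if cos <= attenuated_max:
        return "attenuated"
    return "severe"


def aggregate_homozygous_cos(records: list) -> dict:
    """Mean COS per homozygous mutation.

    All records must be homozygous.  A mutation carried by several patients
    gets the arithmetic mean of their individual COS; a single carrier keeps
    their own COS.  Records whose COS is undefined are skipped.
    """
    sums: dict[str, list] = {}
    for r in records:
        if r.zygosity != "homozygous":
            raise ValidationError(
                f"patient {r.patient_id}: aggregate_homozygous_cos needs "
                "homozygous records only"
            )
        cos = compute_cos(r)
        if cos is None:
            continue
        sums.setdefault(r.allele1, []).append(cos)
    return {m: sum(v) / len(v) for m, v in sums.items()}
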