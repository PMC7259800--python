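"""Table readers/writers, packaged fixtures and the pipeline entry point.

Packaged fixtures transcribe the study's printed tables verbatim: the
region census (table1), the homozygous and compound-heterozygous clinical
cohorts with their domain scores (table4/table5), the same cohorts with
their multiparametric mutation scores (table6/table7), the healthy-control
variant sets (table8 ExAC homozygotes, table9 dbGaP heterozygote pairs) and
the trained parameter weights (table10).  Patient identifiers drift between
the COS and MMS tables in the source material; each fixture is kept
verbatim with its own ``source_label`` and no cross-table merge is
attempted.

Blank domain cells are *missing* ("not mentioned in the case report"), not
zero; readers and writers round-trip that distinction via empty TSV cells.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as _features
from . import simulate as _simulate
from . import stats as _stats
from . import wmms as _wmms
from .cohort import (
    DOMAINS,
    LEGAL_DOMAIN_VALUES,
    PatientRecord,
    classify_severity,
    compute_cos,
    filter_cohort,
)
from .errors import ConfigError, SchemaError, ValidationError
from .wmms import WeightSet, WmmsModel, predict_cohort, unit_weightset

FIXTURES = {
    "table1_regions": "table1_regions.tsv",
    "table4_homozygous_cos": "table4_homozygous_cos.tsv",
    "table5_heterozygous_cos": "table5_heterozygous_cos.tsv",
    "table6_homozygous_mms": "table6_homozygous_mms.tsv",
    "table7_heterozygous_mms": "table7_heterozygous_mms.tsv",
    "table8_exac_controls": "table8_exac_controls.tsv",
    "table9_dbgap_controls": "table9_dbgap_controls.tsv",
    "table10_weights": "table10_weights.tsv",
    "symptom_vocabulary": "symptom_vocabulary.tsv",
    "annotations_examples": "annotations_examples.tsv",
}

COHORT_COLUMNS = [
    "patient_id",
    "zygosity",
    "allele1",
    "allele2",
    "allele1_class",
    "allele2_class",
    "sex",
    "age_years",
    "deceased",
    "seizures",
    "cognitive",
    "brain_malformation",
    "muscle_movement",
]


@dataclass
class CohortTable:
    """A validated list of patient records with a provenance label."""

    rows: list = field(default_factory=list)
    source_label: str = "unlabelled"

    def __len__(self):
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "patient_id": r.patient_id,
                    "zygosity": r.zygosity,
                    "allele1": r.allele1,
                    "allele2": r.allele2,
                    "allele1_class": r.allele1_class,
                    "allele2_class": r.allele2_class,
                    "sex": "" if r.sex == "unknown" else r.sex,
                    "age_years": "" if r.age_years is None else r.age_years,
                    "deceased": r.deceased,
                    **{
                        d: ("" if getattr(r, d) is None else int(getattr(r, d)))
                        for d in DOMAINS
                    },
                }
            )
        return pd.DataFrame(recs, columns=COHORT_COLUMNS)


def _fixture_path(name: str):
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; valid keys: {', '.join(sorted(FIXTURES))}"
        )
    return resources.files("glypheno.data").joinpath(FIXTURES[name])


def load_fixture(name: str) -> pd.DataFrame:
    """Return a packaged table verbatim as a DataFrame."""
    with _fixture_path(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def fixture_checksums() -> dict:
    """SHA-256 of every packaged fixture file (byte-identical across runs)."""
    out = {}
    for name in FIXTURES:
        out[name] = hashlib.sha256(_fixture_path(name).read_bytes()).hexdigest()
    return out


def _parse_domain(value: str, domain: str, row_label: str):
    value = str(value).strip()
    if value in ("", "-"):
        return None
    try:
        iv = int(float(value))
    except ValueError:
        raise ValidationError(
            f"row {row_label}, column {domain}: unreadable value {value!r}"
        )
    if iv not in LEGAL_DOMAIN_VALUES[domain]:
        raise ValidationError(
            f"row {row_label}, column {domain}: illegal value {iv} "
            f"(legal: {sorted(LEGAL_DOMAIN_VALUES[domain])})"
        )
    return iv


def cohort_from_frame(df: pd.DataFrame, source_label: str = "unlabelled") -> CohortTable:
    """Validate a raw cohort frame into a CohortTable.

    Missing domain cells (blank) become unscored (None); explicit 0 stays a
    scored 0 — the two states are distinct.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing required column(s): {missing}")
    ids = list(df["patient_id"].astype(str))
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate patient identifiers: {dupes}")
    rows = []
    for _, rec in df.iterrows():
        pid = str(rec["patient_id"])
        age = str(rec["age_years"]).strip()
        sex = str(rec["sex"]).strip() or "unknown"
        rows.append(
            PatientRecord(
                patient_id=pid,
                zygosity=str(rec["zygosity"]).strip(),
                allele1=str(rec["allele1"]).strip(),
                allele2=str(rec["allele2"]).strip(),
                allele1_class=str(rec["allele1_class"]).strip() or "missense",
                allele2_class=str(rec["allele2_class"]).strip() or "missense",
                sex=sex,
                age_years=float(age) if age else None,
                deceased=str(rec["deceased"]).strip().lower() in ("true", "1", "yes"),
                **{d: _parse_domain(rec[d], d, pid) for d in DOMAINS},
            )
        )
    return CohortTable(rows=rows, source_label=source_label)


def read_cohort_table(path, dialect: str = "tsv") -> CohortTable:
    """Read and validate a cohort table from TSV or CSV."""
    if dialect not in ("tsv", "csv"):
        raise ValidationError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return cohort_from_frame(df, source_label=str(path))


def write_cohort_table(table: CohortTable, path, dialect: str = "tsv"):
    """Write a cohort table; unscored domains become empty cells."""
    sep = "\t" if dialect == "tsv" else ","
    table.to_frame().to_csv(path, sep=sep, index=False)


def fixture_cohort(name: str) -> CohortTable:
    """A packaged clinical cohort (table4/table5) as a validated CohortTable."""
    df = load_fixture(name)
    return cohort_from_frame(df[COHORT_COLUMNS], source_label=name)


def read_annotation_table(path) -> pd.DataFrame:
    """Read a mutation annotation table (TSV)."""
    df = pd.read_csv(path, sep="\t")
    required = [
        "mutation",
        "position",
        "ref_aa",
        "alt_aa",
        "ddg_kcal_mol",
        "conservation_grade",
        "blosum62",
        "sec_struct",
        "active_site",
        "active_region_7A",
        "nterm_plp",
        "h_interface",
        "dimer_interface",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation table missing required column(s): {missing}")
    return df


def read_regions(path) -> dict:
    """Region definitions from JSON: one or a list of {"name", "residues"}."""
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        payload = [payload]
    return {entry["name"]: set(int(r) for r in entry["residues"]) for entry in payload}


def load_weightsets() -> dict:
    """The packaged trained-weight table as WeightSet objects by provenance."""
    df = load_fixture("table10_weights")
    out = {}
    for col, provenance in [
        ("unweighted", "unweighted"),
        ("homozygous_trained", "homozygous_trained"),
        ("heterozygous_trained", "heterozygous_trained"),
    ]:
        weights = pd.Series(
            df[col].astype(float).to_numpy(), index=df["parameter"].to_list()
        )
        out[provenance] = WeightSet(weights=weights, provenance=provenance)
    return out


def write_weights_tsv(ws: WeightSet, path):
    """Serialize a weight set in the printed table's layout."""
    pd.DataFrame(
        {"parameter": ws.weights.index, "weight": ws.weights.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------- #
# pipeline

STAGES = ("cos", "mms", "train", "predict", "stats")


def _control_vectors(seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic parameter vectors for the packaged control variant sets."""
    t8 = load_fixture("table8_exac_controls")
    t9 = load_fixture("table9_dbgap_controls")
    names = set(t8["mutation"])
    for col in ("allele1", "allele2"):
        names |= {n for n in t9[col] if n[0] in _features.STANDARD_AA and n[1:-1].isdigit()}
    ann = _simulate.annotate_mutations(sorted(names), seed=seed)
    homo = pd.DataFrame(
        [_features.derive_parameter_vector(ann[m]) for m in t8["mutation"]]
    )
    homo.index = list(t8["mutation"])
    het_rows = []
    for a1, a2 in zip(t9["allele1"], t9["allele2"]):
        s1 = _features.AlleleSpec(a1, "missense", ann[a1])
        if a2 in ann:
            s2 = _features.AlleleSpec(a2, "missense", ann[a2])
        else:
            s2 = _features.AlleleSpec(a2, "mito_leader")
        het_rows.append(_features.combine_heterozygous(s1, s2))
    het = pd.DataFrame(het_rows)
    het.index = [f"{a}/{b}" for a, b in zip(t9["allele1"], t9["allele2"])]
    return homo, het


def run_pipeline(config: dict, seed: int = 0, out_dir=None) -> dict:
    """Run the requested stages over cohort and annotation inputs.

    ``config`` names the cohort tables (fixture keys or file paths), the
    annotation source ("synthetic" samples reproducible annotations for the
    cohort's mutations from the seed) and the stages to run.  Deterministic
    given a fixed config and seed.  Reports are returned as a dict and, if
    ``out_dir`` is given, written as JSON plus per-table TSVs.
    """
    stages = list(config.get("stages", []))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stage(s): {unknown}")
    if "predict" in stages and "train" not in stages:
        raise ConfigError("stage 'predict' requires stage 'train'")

    report: dict = {"seed": seed, "stages": stages}
    if not stages:
        return _write_report(report, out_dir)

    cohorts = {}
    for role, source in config.get("cohorts", {}).items():
        cohorts[role] = (
            fixture_cohort(source) if source in FIXTURES else read_cohort_table(source)
        )

    ann_source = config.get("annotations", "synthetic")
    missense_names = set()
    for table in cohorts.values():
        for r in table:
            if r.allele1_class == "missense":
                missense_names.add(r.allele1)
            if r.allele2_class == "missense":
                missense_names.add(r.allele2)
    if ann_source == "synthetic":
        annotations = _simulate.annotate_mutations(sorted(missense_names), seed=seed)
    else:
        annotations = _features.annotations_from_frame(read_annotation_table(ann_source))

    scored: dict[str, pd.DataFrame] = {}
    if "cos" in stages:
        cos_report = {}
        for role, table in cohorts.items():
            eligible, log = filter_cohort(list(table))
            rows = [
                {
                    "patient_id": r.patient_id,
                    "cos": compute_cos(r),
                    "severity": classify_severity(compute_cos(r)),
                }
                for r in eligible
            ]
            cos_report[role] = {
                "table": rows,
                "excluded": log,
                "class_counts": dict(
                    pd.Series([row["severity"] for row in rows]).value_counts()
                ),
            }
        report["cos"] = cos_report

    if "mms" in stages:
        unit = unit_weightset()
        mms_report = {}
        for role, table in cohorts.items():
            eligible, _ = filter_cohort(list(table))
            df = predict_cohort(eligible, annotations, unit)
            df = df.rename(columns={"wmms": "mms"})
            scored[role] = df
            mms_report[role] = df.to_dict(orient="records")
        report["mms"] = mms_report

    trained: dict[str, WeightSet] = {}
    if "train" in stages:
        homo_controls, het_controls = _control_vectors(seed)
        train_report = {}
        for role, table in cohorts.items():
            eligible, _ = filter_cohort(list(table))
            zygosity = {r.zygosity for r in eligible}
            if zygosity == {"homozygous"}:
                model = WmmsModel.from_homozygous_cohort(
                    eligible, annotations, controls=homo_controls
                )
            else:
                model = WmmsModel.from_heterozygous_cohort(
                    eligible, annotations, controls=het_controls
                )
            res = model.fit()
            ws = res.to_weightset()
            trained[role] = ws
            train_report[role] = {
                "provenance": ws.provenance,
                "r2": ws.fit_r2,
                "intercept": ws.intercept,
                "weights": {k: float(v) for k, v in ws.weights.items()},
                "pinned_zero": res.pinned_zero,
            }
        report["train"] = train_report

    if "predict" in stages:
        predict_report = {}
        for role, table in cohorts.items():
            eligible, _ = filter_cohort(list(table))
            df = predict_cohort(eligible, annotations, trained[role])
            scored[f"{role}_wmms"] = df
            predict_report[role] = df.to_dict(orient="records")
        report["predict"] = predict_report

    if "stats" in stages:
        stats_report = {}
        for role, table in cohorts.items():
            eligible, _ = filter_cohort(list(table))
            cos_vals = [compute_cos(r) for r in eligible]
            classes = [classify_severity(c) for c in cos_vals]
            entry: dict = {
                "n_patients": len(eligible),
                "class_counts": dict(pd.Series(classes).value_counts()),
            }
            key = f"{role}_wmms" if f"{role}_wmms" in scored else role
            if key in scored:
                df = scored[key]
                score_col = "wmms" if "wmms" in df.columns else "mms"
                merged_classes = [
                    classify_severity(c) for c in df["cos"].astype(int)
                ]
                try:
                    sep = _stats.severity_separation_ttest(
                        df[score_col].to_numpy(), merged_classes
                    )
                    entry["severity_ttest"] = {
                        "t": sep.t,
                        "p": sep.p,
                        "means": sep.means,
                        "sizes": sep.sizes,
                    }
                except ValidationError as err:
                    entry["severity_ttest"] = {"error": str(err)}
                entry["concordance"] = _stats.concordance_counts(
                    df.rename(columns={score_col: "mms"})
                ).to_dict()
            stats_report[role] = entry
        report["stats"] = stats_report

    return _write_report(report, out_dir, scored)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_report(report: dict, out_dir, scored: dict | None = None) -> dict:
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        for name, df in (scored or {}).items():
            df.to_csv(out / f"{name}_scored.tsv", sep="\t", index=False)
    return report
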