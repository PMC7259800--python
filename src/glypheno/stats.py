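"""Cohort-level statistics: region enrichment, phi correlation, severity
separation, MMS/COS concordance and mutation-survey summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError


@dataclass
class RegionEnrichment:
    """Hypergeometric enrichment of mutated residues in a structural region."""

    region: str
    N: int  # residues in the protein
    K: int  # mutated residues in the protein
    n: int  # residues in the region
    k: int  # mutated residues in the region
    rate: float
    p_upper: float


def region_mutation_rate(region_residues: set, mutated_positions: set) -> float:
    """Fraction of the region's residues that carry at least one mutation."""
    region_residues = set(region_residues)
    if not region_residues:
        raise ValidationError("region is empty")
    return len(region_residues & set(mutated_positions)) / len(region_residues)


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), observed k included.

    X counts mutated residues in a size-``n`` region drawn without
    replacement from ``N`` residues of which ``K`` are mutated.  Computed by
    exact summation of the hypergeometric pmf.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValidationError(f"k={k} outside 0..min(K={K}, n={n})")
    denom = comb(N, n)
    total = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return total / denom


def enrichment_table(
    regions: dict, mutated_positions: set, protein_length: int
) -> pd.DataFrame:
    """Per-region mutation rates and upper-tail p-values vs the whole protein."""
    mutated = set(mutated_positions)
    K = len(mutated)
    rows = [
        {
            "region": "whole_protein",
            "total_residues": protein_length,
            "n_mutated": K,
            "rate": K / protein_length,
            "p_upper": np.nan,
        }
    ]
    for name, residues in regions.items():
        residues = set(residues)
        k = len(residues & mutated)
        rows.append(
            {
                "region": name,
                "total_residues": len(residues),
                "n_mutated": k,
                "rate": region_mutation_rate(residues, mutated),
                "p_upper": hypergeom_enrichment(protein_length, K, len(residues), k),
            }
        )
    return pd.DataFrame(rows)


def phi_coefficient(x, y) -> float:
    """Phi correlation of two binary vectors.

    Composite (0.5-valued) entries are binarized at value > 0 before
    computing.  If either vector is constant the coefficient is undefined
    and NaN is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("phi requires equal-length vectors")
    xb = x > 0
    yb = y > 0
    if xb.all() or (~xb).all() or yb.all() or (~yb).all():
        warnings.warn("phi undefined for a constant vector; returning NaN")
        return float("nan")
    n11 = int(np.sum(xb & yb))
    n10 = int(np.sum(xb & ~yb))
    n01 = int(np.sum(~xb & yb))
    n00 = int(np.sum(~xb & ~yb))
    denom = np.sqrt(
        float(n11 + n10) * float(n01 + n00) * float(n11 + n01) * float(n10 + n00)
    )
    return (n11 * n00 - n10 * n01) / denom


def phi_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Square phi-correlation matrix over the columns of a parameter table."""
    cols = list(X.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                out.loc[a, b] = out.loc[b, a] = phi_coefficient(X[a], X[b])
    return out


@dataclass
class SeparationResult:
    """Group means and the severe-vs-attenuated two-sample t-test."""

    means: dict
    sizes: dict
    t: float
    p: float
    welch: bool


def severity_separation_ttest(scores, classes, welch: bool = False) -> SeparationResult:
    """Two-sided Student's t-test of severe vs attenuated WMMS.

    Pooled-variance by default (``welch=True`` for unequal variances).  Means
    and sizes are reported for all three classes present.
    """
    s = pd.Series(np.asarray(scores, dtype=float))
    c = pd.Series(list(classes))
    groups = {g: s[c.values == g].to_numpy() for g in pd.unique(c)}
    for needed in ("severe", "attenuated"):
        if len(groups.get(needed, ())) < 2:
            raise ValidationError(f"class {needed!r} has fewer than 2 members")
    t, p = sps.ttest_ind(groups["severe"], groups["attenuated"], equal_var=not welch)
    return SeparationResult(
        means={g: float(v.mean()) for g, v in groups.items()},
        sizes={g: int(len(v)) for g, v in groups.items()},
        t=float(t),
        p=float(p),
        welch=welch,
    )


def concordance_counts(
    table: pd.DataFrame,
    cos_col: str = "cos",
    mms_col: str = "mms",
    cos_boundary: float = 5,
    mms_threshold: float = 5,
) -> pd.DataFrame:
    """2×2 counts of COS class (low: ≤ boundary, severe: > boundary) against
    MMS class (low: < threshold, high: ≥ threshold)."""
    for col in (cos_col, mms_col):
        if col not in table.columns:
            raise ValidationError(f"column {col!r} missing from table")
    cos = table[cos_col].astype(float)
    mms = table[mms_col].astype(float)
    low_cos = cos <= cos_boundary
    high_mms = mms >= mms_threshold
    return pd.DataFrame(
        {
            "mms_low": [
                int((low_cos & ~high_mms).sum()),
                int((~low_cos & ~high_mms).sum()),
            ],
            "mms_high": [
                int((low_cos & high_mms).sum()),
                int((~low_cos & high_mms).sum()),
            ],
        },
        index=["cos_low", "cos_severe"],
    )


def mutation_survey(mutations, top_k: int = 10) -> dict:
    """Counts of unique mutations and residues, and the most-mutated positions.

    ``mutations`` is an iterable of ``(position, ref, alt)`` triples.  Ties in
    the per-position frequency ranking are broken by ascending position.
    """
    muts = {(int(p), r, a) for p, r, a in mutations}
    positions = [p for p, _, _ in muts]
    counts = pd.Series(positions).value_counts()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {
        "n_mutations": len(muts),
        "n_residues": len(set(positions)),
        "top_positions": ranked[:top_k],
        "per_position": dict(counts.sort_index()),
    }
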