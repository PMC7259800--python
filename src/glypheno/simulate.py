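"""Synthetic annotation tables, patient cohorts and docking decoy sets.

The generators reproduce the statistical structure the analysis assumes so
that every downstream stage is testable without external downloads:

* annotation tables with disjoint structural regions sized like the real
  protein's (active site 30, N-terminal PLP pocket 20, H-protein interface
  17 residues of 1020) and predicted-ΔΔG effects drawn from the five
  stability bins at the observed proportions (42/63/96/35/15 of 251);
* patient cohorts whose clinical outcome score is a noisy linear function
  of the mutation parameter vector, with the latent truth retained for
  parameter-recovery tests;
* geometric-toy docking decoy sets with one planted pose that contacts a
  high-conservation patch and minimizes the ligand–site distance, so the
  rescoring pipeline has a known right answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as _features
from .cohort import PatientRecord
from .errors import ValidationError
from .features import (
    ALL_PARAMETERS,
    FeatureConfig,
    MutationAnnotation,
    blosum62_score,
    unit_signs,
)

_AA = sorted(_features.STANDARD_AA)

#: Mix of non-missense second-allele classes among compound heterozygotes,
#: as observed in the clinical cohort (15 splice, 8 deletion, 8 nonsense,
#: 1 mitochondrial-leader of 32).
NON_MISSENSE_MIX = {
    "intronic_splice": 15 / 32,
    "deletion": 8 / 32,
    "nonsense_frameshift": 8 / 32,
    "mito_leader": 1 / 32,
}


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic generators.

    Region sizes and the mutation census match the real protein; the ΔΔG
    mixture follows the five stability bins; the cohort size and zygosity
    mix match the 74-patient clinical cohort (24 homozygous, 50 compound
    heterozygous, 32 of the latter with one non-missense allele).
    """

    seed: int = 0
    protein_length: int = 1020
    region_sizes: dict = field(
        default_factory=lambda: {
            "active_site": 30,
            "active_region": 40,
            "nterm_plp": 20,
            "h_interface": 17,
            "dimer_interface": 30,
        }
    )
    n_mutations: int = 251
    ddg_bin_counts: tuple = (42, 63, 96, 35, 15)  # very-destab .. very-stab
    sec_struct_probs: tuple = (0.35, 0.25, 0.40)  # helix, sheet, loop
    true_weights: pd.Series = field(default_factory=unit_signs)
    noise_sd: float = 1.0
    n_patients: int = 74
    homozygous_fraction: float = 24 / 74
    non_missense_fraction: float = 32 / 50

    def validate(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_mutations > self.protein_length * 19:
            raise ValidationError("n_mutations exhausts the substitution space")
        if not 0 <= self.homozygous_fraction <= 1:
            raise ValidationError("homozygous_fraction must be in [0, 1]")


_DDG_BIN_RANGES = [(-9.0, -5.0), (-5.0, -1.5), (-1.5, 1.5), (1.5, 5.0), (5.0, 9.0)]


def _sample_regions(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    """Disjoint residue sets for the structural regions."""
    sizes = cfg.region_sizes
    total = sum(sizes.values())
    picks = rng.choice(np.arange(1, cfg.protein_length + 1), size=total, replace=False)
    regions, start = {}, 0
    for name, size in sizes.items():
        regions[name] = set(int(p) for p in picks[start : start + size])
        start += size
    return regions


def _random_substitution(rng: np.random.Generator) -> tuple:
    ref = _AA[rng.integers(len(_AA))]
    alt = ref
    while alt == ref:
        alt = _AA[rng.integers(len(_AA))]
    return ref, alt


def simulate_annotations(
    cfg: SimulationConfig | None = None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Sample a mutation annotation table in the package's TSV schema.

    Unique (position, ref, alt) triples; region flags from disjoint region
    sets; ΔΔG from the five-bin mixture; conservation grades uniform 1..9;
    BLOSUM62 computed from the sampled substitution.  The region residue
    sets are attached as ``df.attrs['regions']``.
    """
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    regions = _sample_regions(cfg, rng)
    probs = np.array(cfg.ddg_bin_counts, dtype=float)
    probs /= probs.sum()

    seen, rows = set(), []
    while len(rows) < cfg.n_mutations:
        pos = int(rng.integers(1, cfg.protein_length + 1))
        ref, alt = _random_substitution(rng)
        if (pos, ref, alt) in seen:
            continue
        seen.add((pos, ref, alt))
        bin_idx = int(rng.choice(5, p=probs))
        lo, hi = _DDG_BIN_RANGES[bin_idx]
        ddg = float(rng.uniform(lo, hi))
        sec = ("helix", "sheet", "loop")[
            int(rng.choice(3, p=np.array(cfg.sec_struct_probs)))
        ]
        rows.append(
            {
                "mutation": f"{ref}{pos}{alt}",
                "position": pos,
                "ref_aa": ref,
                "alt_aa": alt,
                "ddg_kcal_mol": round(ddg, 3),
                "conservation_grade": int(rng.integers(1, 10)),
                "blosum62": blosum62_score(ref, alt),
                "sec_struct": sec,
                "active_site": int(pos in regions["active_site"]),
                "active_region_7A": int(pos in regions["active_region"]),
                "nterm_plp": int(pos in regions["nterm_plp"]),
                "h_interface": int(pos in regions["h_interface"]),
                "dimer_interface": int(pos in regions["dimer_interface"]),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["regions"] = regions
    return df


def annotations_dict(df: pd.DataFrame) -> dict:
    """Annotation-table rows as MutationAnnotation objects keyed by name."""
    return _features.annotations_from_frame(df)


def annotate_mutations(
    names, seed: int = 0, cfg: SimulationConfig | None = None
) -> dict:
    """Plausible annotations for named mutations (e.g. ``R515S``).

    Position, ref and alt are parsed from the name; structural and
    conservation facts are sampled reproducibly from the seed.  Useful for
    exercising the pipeline on cohort fixtures whose full annotation table
    is not packaged.
    """
    cfg = cfg or SimulationConfig(seed=seed)
    rng = np.random.default_rng(seed)
    regions = _sample_regions(cfg, rng)
    probs = np.array(cfg.ddg_bin_counts, dtype=float)
    probs /= probs.sum()
    out = {}
    for name in names:
        ref, alt = name[0], name[-1]
        pos = int(name[1:-1])
        bin_idx = int(rng.choice(5, p=probs))
        lo, hi = _DDG_BIN_RANGES[bin_idx]
        out[name] = MutationAnnotation(
            mutation=name,
            position=pos,
            ref_aa=ref,
            alt_aa=alt,
            ddg_kcal_mol=float(rng.uniform(lo, hi)),
            conservation_grade=int(rng.integers(1, 10)),
            blosum62=blosum62_score(ref, alt),
            sec_struct=("helix", "sheet", "loop")[int(rng.integers(3))],
            active_site=pos in regions["active_site"],
            active_region_7A=pos in regions["active_region"],
            nterm_plp=pos in regions["nterm_plp"],
            h_interface=pos in regions["h_interface"],
            dimer_interface=pos in regions["dimer_interface"],
        )
    return out


def decompose_cos(cos: int) -> dict:
    """Deterministic split of a COS into four legal domain scores.

    Greedy fill: brain malformation (3 if at least 3 remain), then seizures
    ({0,1,3}), then cognitive, then muscle/movement.  Any decomposition
    consistent with the legal domain sets suffices for testing; this one is
    a documented convention, not clinically derived.
    """
    cos = int(cos)
    if not 0 <= cos <= 12:
        raise ValidationError(f"COS {cos} out of range")
    brain = 3 if cos >= 3 else 0
    rem = cos - brain
    seiz = 3 if rem >= 3 else (1 if rem >= 1 else 0)
    rem -= seiz
    cog = min(3, rem)
    rem -= cog
    mus = min(3, rem)
    rem -= mus
    assert rem == 0
    return {
        "brain_malformation": brain,
        "seizures": seiz,
        "cognitive": cog,
        "muscle_movement": mus,
    }


def simulate_cohort(
    cfg: SimulationConfig | None = None,
    annotations: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
    feature_cfg: FeatureConfig | None = None,
) -> tuple[list, dict]:
    """Sample a patient cohort whose COS is a noisy linear score.

    Genotypes are drawn from the annotation table per the zygosity mix; the
    latent score is Σ w*·v + ε with ε ~ N(0, noise_sd²); the observed COS is
    the latent score rounded and clipped to [0, 12] (noise enters before the
    discretization, as in the real scale), then decomposed into the four
    domains.  Returns the records and a latent-truth sidecar with the true
    weights, per-patient vectors, latent scores and noise draws.
    """
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    if annotations is None:
        annotations = simulate_annotations(cfg, rng)
    ann = annotations_dict(annotations)
    names = list(ann)
    w = cfg.true_weights.reindex(ALL_PARAMETERS).fillna(0.0)

    records, vectors, latents, cos_values = [], [], [], []
    nm_classes = list(NON_MISSENSE_MIX)
    nm_probs = np.array([NON_MISSENSE_MIX[c] for c in nm_classes])
    for i in range(cfg.n_patients):
        pid = f"sim{i:04d}"
        homozygous = rng.random() < cfg.homozygous_fraction
        m1 = names[rng.integers(len(names))]
        a1 = _features.AlleleSpec(m1, "missense", ann[m1])
        if homozygous:
            v = _features.allele_vector(a1, feature_cfg)
            allele2, class2 = m1, "missense"
        else:
            if rng.random() < cfg.non_missense_fraction:
                class2 = nm_classes[int(rng.choice(len(nm_classes), p=nm_probs))]
                allele2 = f"{class2}_allele"
                a2 = _features.AlleleSpec(allele2, class2)
            else:
                allele2 = names[rng.integers(len(names))]
                class2 = "missense"
                a2 = _features.AlleleSpec(allele2, "missense", ann[allele2])
            v = _features.combine_heterozygous(a1, a2, feature_cfg)
        latent = float(w @ v.reindex(w.index)) + float(rng.normal(0.0, cfg.noise_sd))
        cos = int(np.clip(np.round(latent), 0, 12))
        domains = decompose_cos(cos)
        records.append(
            PatientRecord(
                patient_id=pid,
                zygosity="homozygous" if homozygous else "compound_heterozygous",
                allele1=m1,
                allele2=allele2,
                allele1_class="missense",
                allele2_class=class2,
                deceased=False,
                **domains,
            )
        )
        v.name = pid
        vectors.append(v)
        latents.append(latent)
        cos_values.append(cos)

    truth = {
        "true_weights": w,
        "noise_sd": cfg.noise_sd,
        "vectors": pd.DataFrame(vectors),
        "latent": np.array(latents),
        "cos": np.array(cos_values),
    }
    return records, truth


# --------------------------------------------------------------------------- #
# docking decoys


@dataclass
class DockingSimulation:
    """A synthetic decoy set with its known right answer."""

    pdb_text: str
    cons_a: dict
    cons_b: dict
    planted_model_id: str
    site_residues: set
    ligand: tuple  # (chain, resnum, atom_name)
    mobile_chain: str = "B"


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _atom_line(serial, name, resname, chain, resnum, xyz) -> str:
    return (
        f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {chain}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {name.strip()[0]:>2s}"
    )


def simulate_docking_set(
    n_models: int = 20,
    seed: int = 0,
    n_receptor: int = 60,
    radius: float = 20.0,
    patch_size: int = 5,
) -> DockingSimulation:
    """Rigid random placements of a small mobile chain around a fixed chain.

    The fixed chain A is one Cα per residue on a sphere; the ``patch_size``
    residues nearest the pole carry conservation grade 9 (the others ≤ 6)
    and double as the target site.  The mobile chain B is a 5-residue radial
    stalk whose tip (grade 9) is the ligand.  Decoy 0 is the planted pose:
    it touches the central patch residue with only its tip in contact, so it
    strictly maximizes both conservation parameters and minimizes the
    ligand–site distance.  The remaining poses target low-conservation
    residues far from the pole and sit deeper, dragging a lower-grade stalk
    residue into the interface.
    """
    if n_models < 2:
        raise ValidationError("need at least 2 models")
    rng = np.random.default_rng(seed)
    dirs = _fibonacci_sphere(n_receptor)
    order = np.argsort(-dirs[:, 2])
    patch_idx = set(int(i) for i in order[:patch_size])
    central = int(order[0])

    cons_a = {}
    for i in range(n_receptor):
        cons_a[i + 1] = 9 if i in patch_idx else int(rng.integers(1, 7))
    cons_b = {1: 9, 2: 5, 3: 4, 4: 3, 5: 2}

    eligible = [
        i for i in range(n_receptor) if i not in patch_idx and dirs[i, 2] < 0.3
    ]
    targets = [central] + [
        int(eligible[j]) for j in rng.choice(len(eligible), size=n_models - 1)
    ]
    gaps = [3.5] + list(rng.uniform(0.8, 1.4, size=n_models - 1))

    lines = []
    for mi, (ti, gap) in enumerate(zip(targets, gaps)):
        lines.append(f"MODEL     {mi + 1:4d}")
        serial = 1
        for ri in range(n_receptor):
            lines.append(
                _atom_line(serial, " CA ", "ALA", "A", ri + 1, radius * dirs[ri])
            )
            serial += 1
        u = dirs[ti]
        for bj in range(5):
            xyz = (radius + gap + 2.5 * bj) * u
            lines.append(_atom_line(serial, " CA ", "GLY", "B", bj + 1, xyz))
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")

    return DockingSimulation(
        pdb_text="\n".join(lines) + "\n",
        cons_a=cons_a,
        cons_b=cons_b,
        planted_model_id="model_000",
        site_residues={i + 1 for i in patch_idx},
        ligand=("B", 1, "CA"),
    )
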