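"""Rescoring of two-chain docking decoys by interface conservation and
ligand–site distance.

Candidate rigid-body poses of a binary complex (e.g. the H-protein shuttle
docked onto the glycine decarboxylase surface) are re-ranked with up to three
equally weighted parameters: mean evolutionary conservation of each partner's
interface residues, and the distance of a designated ligand atom (the
lipoyllysine of H-protein) from a designated site (the active-site tunnel
entry).  Interface residues are those with any atom within a cutoff
(default 4 Å) of the partner chain.  Each parameter is min–max normalized
across the decoy set to [0, 1] — the best model per parameter scores 1, the
worst 0 (distance is inverted so that closer is better) — and the total is
the sum of the available normalized parameters.  A second, constrained round
restricts the decoys to a neighbourhood of the first round's best pose and
recomputes the normalization on the subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError


@dataclass
class DockingModel:
    """One rigid two-chain decoy: ``atoms`` has columns chain, resnum,
    resname, atom_name, x, y, z."""

    model_id: str
    atoms: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        chains = self.atoms["chain"].unique()
        if len(chains) < 2:
            raise ValidationError(
                f"model {self.model_id}: needs >= 2 chains, found {list(chains)}"
            )
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.isfinite(xyz).all():
            raise ValidationError(f"model {self.model_id}: non-finite coordinates")

    def chain(self, chain_id: str) -> pd.DataFrame:
        sel = self.atoms[self.atoms["chain"] == chain_id]
        if sel.empty:
            raise ValidationError(f"model {self.model_id}: no chain {chain_id!r}")
        return sel

    def chain_centroid(self, chain_id: str) -> np.ndarray:
        return self.chain(chain_id)[["x", "y", "z"]].to_numpy(dtype=float).mean(axis=0)


def parse_models(path) -> list[DockingModel]:
    """Read a (multi-model) PDB file into one DockingModel per MODEL block.

    Waters are dropped; other heteroatoms are retained.  Unreadable records
    are skipped by the underlying parser.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("decoys", str(path))
    models = []
    for mdl in structure:
        rows = []
        for ch in mdl:
            for res in ch:
                if res.get_resname().strip() in ("HOH", "WAT"):
                    continue
                for atom in res:
                    x, y, z = atom.coord
                    rows.append(
                        {
                            "chain": ch.id,
                            "resnum": res.id[1],
                            "resname": res.get_resname().strip(),
                            "atom_name": atom.get_name(),
                            "x": float(x),
                            "y": float(y),
                            "z": float(z),
                        }
                    )
        models.append(DockingModel(model_id=f"model_{mdl.id:03d}", atoms=pd.DataFrame(rows)))
    if not models:
        raise ValidationError(f"no models found in {path}")
    return models


def interface_residues(
    m: DockingModel, chain_a: str, chain_b: str, cutoff: float = 4.0
) -> tuple[set, set]:
    """Residues of each chain with any atom within ``cutoff`` Å of the partner.

    Grid-accelerated (KD-tree); identical by construction to the all-pairs
    definition.
    """
    A = m.chain(chain_a)
    B = m.chain(chain_b)
    xa = A[["x", "y", "z"]].to_numpy(dtype=float)
    xb = B[["x", "y", "z"]].to_numpy(dtype=float)
    pairs = cKDTree(xa).query_ball_tree(cKDTree(xb), r=cutoff)
    res_a, res_b = set(), set()
    resnum_a = A["resnum"].to_numpy()
    resnum_b = B["resnum"].to_numpy()
    for ia, hits in enumerate(pairs):
        if hits:
            res_a.add(int(resnum_a[ia]))
            res_b.update(int(resnum_b[ib]) for ib in hits)
    return res_a, res_b


def conservation_parameter(
    residues: set, table: dict, aggregator=np.mean
) -> float | None:
    """Aggregate (default mean) conservation grade over an interface set.

    Residues missing from the table are excluded with a warning; an empty
    set yields ``None`` (the model stays scorable on other parameters).
    """
    residues = set(residues)
    if not residues:
        return None
    known = [table[r] for r in residues if r in table]
    missing = residues - set(table)
    if missing:
        warnings.warn(
            f"{len(missing)} interface residues missing from conservation table"
        )
    if not known:
        return None
    return float(aggregator(known))


def distance_parameter(
    m: DockingModel,
    ligand: tuple,
    site_residues: set,
    site_chain: str,
) -> float | None:
    """Distance (Å) from a ligand atom to the Cα centroid of the site residues.

    ``ligand`` is ``(chain, resnum, atom_name)``.  A missing ligand atom or an
    empty site yields ``None`` with a warning.
    """
    lig_chain, lig_res, lig_atom = ligand
    sel = m.atoms[
        (m.atoms["chain"] == lig_chain)
        & (m.atoms["resnum"] == lig_res)
        & (m.atoms["atom_name"] == lig_atom)
    ]
    if sel.empty:
        warnings.warn(f"model {m.model_id}: ligand atom {ligand} not found")
        return None
    if not site_residues:
        raise ValidationError("site residue set is empty")
    site = m.chain(site_chain)
    ca = site[(site["resnum"].isin(set(site_residues))) & (site["atom_name"] == "CA")]
    if ca.empty:
        warnings.warn(f"model {m.model_id}: no Cα atoms for site residues")
        return None
    centroid = ca[["x", "y", "z"]].to_numpy(dtype=float).mean(axis=0)
    lig_xyz = sel[["x", "y", "z"]].to_numpy(dtype=float)[0]
    return float(np.linalg.norm(lig_xyz - centroid))


def score_models(
    models: list,
    cons_a: dict,
    cons_b: dict,
    chain_a: str = "A",
    chain_b: str = "B",
    cutoff: float = 4.0,
    ligand: tuple | None = None,
    site_residues: set | None = None,
) -> pd.DataFrame:
    """Raw ranking parameters for every decoy.

    ``cons_a``/``cons_b`` map residue number to conservation grade per chain
    role.  If ``ligand`` and ``site_residues`` are given, the ligand–site
    distance is measured on chain ``chain_a``.
    """
    rows = []
    for m in models:
        res_a, res_b = interface_residues(m, chain_a, chain_b, cutoff)
        row = {
            "model_id": m.model_id,
            "raw_cons_a": conservation_parameter(res_a, cons_a),
            "raw_cons_b": conservation_parameter(res_b, cons_b),
        }
        if ligand is not None and site_residues is not None:
            row["raw_distance"] = distance_parameter(m, ligand, site_residues, chain_a)
        rows.append(row)
    return pd.DataFrame(rows)


_RAW_PARAMS = {
    "raw_cons_a": ("norm_cons_a", False),
    "raw_cons_b": ("norm_cons_b", False),
    "raw_distance": ("norm_distance", True),  # lower distance is better
}


def normalize_and_rank(raw: pd.DataFrame, use_distance: bool = True) -> pd.DataFrame:
    """Min–max normalize each raw parameter to [0, 1] and rank by total.

    The best model in a parameter scores 1, the worst 0; distance is
    inverted.  A parameter that is constant across the set (or has < 2
    finite values) is dropped with a warning rather than divided by zero.
    Ranking is descending by total with ties broken by model_id.
    """
    if len(raw) < 2:
        raise ValidationError("need at least 2 models to normalize")
    out = raw.copy()
    total = np.zeros(len(out))
    used = []
    for col, (norm_col, invert) in _RAW_PARAMS.items():
        if col not in out.columns or (col == "raw_distance" and not use_distance):
            continue
        vals = pd.to_numeric(out[col], errors="coerce")
        finite = vals.dropna()
        if len(finite) < 2 or finite.max() == finite.min():
            warnings.warn(f"parameter {col} is degenerate; dropped from ranking")
            continue
        norm = (vals - finite.min()) / (finite.max() - finite.min())
        if invert:
            norm = 1.0 - norm
        out[norm_col] = norm
        total += norm.fillna(0.0).to_numpy()
        used.append(norm_col)
    out["total"] = total
    out = out.sort_values(["total", "model_id"], ascending=[False, True]).reset_index(
        drop=True
    )
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["parameters_used"] = used
    return out


def constrained_rescore(
    models: list,
    raw: pd.DataFrame,
    anchor_id: str,
    mobile_chain: str = "B",
    radius: float = 20.0,
    use_distance: bool = True,
) -> pd.DataFrame:
    """Second-round rescoring constrained to the anchor pose's neighbourhood.

    Keeps models whose mobile-chain centroid lies within ``radius`` Å of the
    anchor model's mobile-chain centroid, then recomputes the min–max
    normalization on that subset.  A subset smaller than 2 is returned
    unranked with a warning.
    """
    by_id = {m.model_id: m for m in models}
    if anchor_id not in by_id:
        raise ValidationError(f"anchor {anchor_id!r} not among the models")
    anchor_c = by_id[anchor_id].chain_centroid(mobile_chain)
    keep = [
        mid
        for mid in raw["model_id"]
        if np.linalg.norm(by_id[mid].chain_centroid(mobile_chain) - anchor_c) <= radius
    ]
    subset = raw[raw["model_id"].isin(keep)].reset_index(drop=True)
    if len(subset) < 2:
        warnings.warn("constrained subset has < 2 models; returned unranked")
        return subset
    return normalize_and_rank(subset, use_distance=use_distance)
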