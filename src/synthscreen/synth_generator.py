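"""Synthetic protein generation and deterministic binding rules.

A synthetic protein is a point cloud of typed pseudo-residues
``{(x_i, y_i, z_i, t_i)}`` sampled uniformly in a padded box around a ligand.
Two deterministic rules label the resulting complex:

* **Polar** — residues are typed HBA/HBD; the complex is active iff any
  complementary residue/atom pair (HBD residue with an acceptor atom, HBA
  residue with a donor atom) lies strictly within a distance cutoff
  (default 4 Å).
* **Contribution** — residues are typed HBA/HBD/Hydrophobic; every
  type-matched pair contributes ``w * f(d)`` where ``f`` is the Gamma(4, 1)
  probability density of the pair distance ``d`` and ``w`` is 10 for
  hydrogen bonds and 3 for hydrophobic contacts.  The complex is active iff
  the summed score exceeds a threshold (default 4).

Because the rules are exact, the ground-truth importance of every ligand
atom is known: a binary participation indicator under the Polar rule and the
atom's summed pair score under the Contribution rule.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.spatial.distance import cdist

from synthscreen.ligand_chem import (
    ACCEPTOR,
    DONOR,
    HYDROPHOBE,
    Ligand,
    PharmacophoreAssignment,
    assign_pharmacophores,
    load_ligands,
    write_sdf,
)

#: synthetic residue type labels
HBA = "HBA"
HBD = "HBD"
HYDROPHOBIC = "Hydrophobic"

POLAR_RESIDUE_TYPES = (HBA, HBD)
CONTRIBUTION_RESIDUE_TYPES = (HBA, HBD, HYDROPHOBIC)

#: complementary pairing used by the Polar rule (donor binds acceptor)
POLAR_PARTNER = {HBD: ACCEPTOR, HBA: DONOR}
#: same-name matching used by the Contribution rule
CONTRIBUTION_PARTNER = {HBA: ACCEPTOR, HBD: DONOR, HYDROPHOBIC: HYDROPHOBE}

_PDB_RESNAME = {HBA: "HBA", HBD: "HBD", HYDROPHOBIC: "HPH"}
_PDB_RESNAME_INV = {v: k for k, v in _PDB_RESNAME.items()}


class RejectedLigandError(ValueError):
    """Ligand has no functional group able to interact under the rule."""


class GenerationError(RuntimeError):
    """Residue sampling failed repeatedly (e.g. zero survivors)."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned sampling box around a ligand, padded per axis."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    @property
    def lengths(self) -> np.ndarray:
        return np.asarray(self.hi) - np.asarray(self.lo)

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return np.all((pts >= np.asarray(self.lo)) & (pts <= np.asarray(self.hi)), axis=1)


@dataclass(frozen=True)
class SyntheticProtein:
    """Typed pseudo-residue point cloud; one single-atom residue per row."""

    coords: np.ndarray  # (n_res, 3) float, Å
    types: tuple[str, ...]

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coords", coords)
        if coords.shape[0] != len(self.types):
            raise ValueError("coordinate/type length mismatch")

    @property
    def n_res(self) -> int:
        return len(self.types)


@dataclass(frozen=True)
class InteractionRecord:
    residue_idx: int
    atom_idx: int
    kind: str  # "HBond" | "Hydrophobic"
    distance: float
    score: float  # 0 under the Polar rule


@dataclass(frozen=True)
class GenerationConfig:
    """Parameters of the generative process and the binding rules.

    Distances are in Å.  ``a_coef`` is the candidate-point density in
    residues per Å³ used in step 2 of the protocol (the sampled count is
    ``round(a_coef * box volume)``); ``n_ops`` caps the residue count at
    ``floor(n_ops / n_lig)`` so that ligands with many functional groups do
    not see systematically more partners.
    """

    rule: str = "polar"
    pad: float = 5.0
    clash_dist: float = 2.0
    min_sep: float = 3.0
    polar_cutoff: float = 4.0
    a_coef: float = 0.05
    n_ops: int = 50
    score_threshold: float = 4.0
    hb_weight: float = 10.0
    hydrophobic_weight: float = 3.0
    gamma_shape: float = 4.0
    gamma_rate: float = 1.0
    max_sample_attempts: int = 10

    def __post_init__(self):
        if self.rule not in ("polar", "contribution"):
            raise ValueError(f"unknown rule {self.rule!r}")
        for name in ("pad", "clash_dist", "min_sep", "polar_cutoff", "a_coef"):
            if getattr(self, name) <= 0 and name != "pad":
                raise ValueError(f"{name} must be positive")
        if self.n_ops < 1:
            raise ValueError("n_ops must be >= 1")
        if self.hb_weight <= 0 or self.hydrophobic_weight <= 0:
            raise ValueError("interaction weights must be positive")

    @property
    def residue_types(self) -> tuple[str, ...]:
        return POLAR_RESIDUE_TYPES if self.rule == "polar" else CONTRIBUTION_RESIDUE_TYPES


@dataclass
class SyntheticComplex:
    """A ligand, its synthetic protein, the rule label and the ground truth."""

    ligand: Ligand
    assignment: PharmacophoreAssignment
    protein: SyntheticProtein
    rule: str
    label: str  # "active" | "inactive"
    atom_contributions: np.ndarray  # binary indicators (polar) or scores
    records: tuple[InteractionRecord, ...]
    config: GenerationConfig
    seed: int | None = None
    total_score: float | None = None  # contribution rule only

    @property
    def is_active(self) -> bool:
        return self.label == "active"

    @property
    def id(self) -> str:
        return self.ligand.id


def make_box(ligand: Ligand, pad: float = 5.0) -> Box:
    """Pad the ligand's heavy-atom bounding box by ``pad`` Å per side."""
    xyz = ligand.coords()
    lo = xyz.min(axis=0) - pad
    hi = xyz.max(axis=0) + pad
    return Box(lo=tuple(lo), hi=tuple(hi))


def sample_synthetic_protein(
    ligand: Ligand,
    assignment: PharmacophoreAssignment,
    config: GenerationConfig,
    seed: int,
) -> SyntheticProtein:
    """Sample a typed residue cloud around the ligand.

    Protocol: sample ``round(a_coef * volume)`` uniform points in the padded
    box with uniformly random types; delete points within ``clash_dist`` of
    any ligand atom; greedily (in sampling order) delete points within
    ``min_sep`` of an already retained point; if more than
    ``floor(n_ops / n_lig)`` survive, subsample uniformly to that count.
    Deterministic for a fixed seed.
    """
    if assignment.n_lig == 0:
        raise RejectedLigandError(
            f"ligand {ligand.id!r} has no interacting functional group under "
            f"rule {config.rule!r}"
        )
    xyz = ligand.coords()
    box = make_box(ligand, config.pad)
    n_res_cap = config.n_ops // assignment.n_lig
    type_set = config.residue_types
    rng = np.random.default_rng(seed)
    for _ in range(config.max_sample_attempts):
        m = int(round(config.a_coef * box.volume))
        pts = rng.uniform(box.lo, box.hi, size=(m, 3))
        types = rng.integers(0, len(type_set), size=m)
        # clash filter: strict < deletes, >= keeps
        if m:
            keep = cdist(pts, xyz).min(axis=1) >= config.clash_dist
            pts, types = pts[keep], types[keep]
        # greedy pairwise-separation filter in sampling order
        kept_idx: list[int] = []
        for i in range(len(pts)):
            if all(
                np.linalg.norm(pts[i] - pts[j]) >= config.min_sep for j in kept_idx
            ):
                kept_idx.append(i)
        pts, types = pts[kept_idx], types[kept_idx]
        if len(pts) > n_res_cap:
            chosen = np.sort(rng.choice(len(pts), size=n_res_cap, replace=False))
            pts, types = pts[chosen], types[chosen]
        if len(pts) > 0 or n_res_cap == 0:
            return SyntheticProtein(
                coords=pts, types=tuple(type_set[t] for t in types)
            )
    raise GenerationError(
        f"no residues survived filtering for ligand {ligand.id!r} after "
        f"{config.max_sample_attempts} attempts"
    )


def interaction_score(
    interaction_type: str, d: float, config: GenerationConfig | None = None
) -> float:
    """Distance-dependent pair score ``w * f(d)`` of the Contribution rule.

    ``f`` is the Gamma(shape, rate) probability density (default
    Gamma(4, 1), i.e. ``d^3 e^{-d} / 6``, unimodal with mode at 3 Å) and
    ``w`` is 10 for hydrogen bonds, 3 for hydrophobic contacts.
    """
    if config is None:
        config = GenerationConfig(rule="contribution")
    if d <= 0:
        raise ValueError(f"pair distance must be positive, got {d}")
    if interaction_type == "HBond":
        w = config.hb_weight
    elif interaction_type == "Hydrophobic":
        w = config.hydrophobic_weight
    else:
        raise ValueError(f"unknown interaction type {interaction_type!r}")
    k, rate = config.gamma_shape, config.gamma_rate
    pdf = rate**k * d ** (k - 1) * math.exp(-rate * d) / math.gamma(k)
    return w * pdf


def _pair_distances(ligand: Ligand, protein: SyntheticProtein) -> np.ndarray:
    if protein.n_res == 0:
        return np.zeros((0, ligand.mol.GetNumAtoms()))
    return cdist(protein.coords, ligand.coords())


def evaluate_polar(
    ligand: Ligand,
    assignment: PharmacophoreAssignment,
    protein: SyntheticProtein,
    config: GenerationConfig,
) -> tuple[str, tuple[InteractionRecord, ...], np.ndarray]:
    """Apply the Polar rule: active iff any complementary pair is < cutoff.

    Returns the label, one record per interacting pair, and per-atom binary
    participation indicators.
    """
    if assignment.rule != "polar":
        raise ValueError("assignment was not made with rule='polar'")
    dists = _pair_distances(ligand, protein)
    n_atoms = ligand.mol.GetNumAtoms()
    records: list[InteractionRecord] = []
    indicators = np.zeros(n_atoms)
    for r in range(protein.n_res):
        partner = POLAR_PARTNER[protein.types[r]]
        for a in range(n_atoms):
            if partner in assignment.atom_types[a] and dists[r, a] < config.polar_cutoff:
                records.append(
                    InteractionRecord(
                        residue_idx=r,
                        atom_idx=a,
                        kind="HBond",
                        distance=float(dists[r, a]),
                        score=0.0,
                    )
                )
                indicators[a] = 1.0
    label = "active" if records else "inactive"
    return label, tuple(records), indicators


def evaluate_contribution(
    ligand: Ligand,
    assignment: PharmacophoreAssignment,
    protein: SyntheticProtein,
    config: GenerationConfig,
) -> tuple[str, tuple[InteractionRecord, ...], np.ndarray, float]:
    """Apply the Contribution rule: active iff the summed score exceeds the
    threshold.

    Every type-matched pair contributes at any distance (the Gamma pdf decays
    naturally); mismatched pairs score 0 and emit no record.  Returns the
    label, records, per-atom summed scores and the total.
    """
    if assignment.rule != "contribution":
        raise ValueError("assignment was not made with rule='contribution'")
    dists = _pair_distances(ligand, protein)
    n_atoms = ligand.mol.GetNumAtoms()
    records: list[InteractionRecord] = []
    contributions = np.zeros(n_atoms)
    for r in range(protein.n_res):
        rtype = protein.types[r]
        partner = CONTRIBUTION_PARTNER[rtype]
        kind = "Hydrophobic" if rtype == HYDROPHOBIC else "HBond"
        for a in range(n_atoms):
            if partner in assignment.atom_types[a]:
                d = float(dists[r, a])
                s = interaction_score(kind, d, config)
                records.append(
                    InteractionRecord(
                        residue_idx=r, atom_idx=a, kind=kind, distance=d, score=s
                    )
                )
                contributions[a] += s
    total = float(contributions.sum())
    label = "active" if total > config.score_threshold else "inactive"
    return label, tuple(records), contributions, total


def generate_complex(
    ligand: Ligand, config: GenerationConfig, seed: int
) -> SyntheticComplex:
    """Sample a synthetic protein for the ligand and label the complex."""
    assignment = assign_pharmacophores(ligand, config.rule)
    protein = sample_synthetic_protein(ligand, assignment, config, seed)
    if config.rule == "polar":
        label, records, contributions = evaluate_polar(
            ligand, assignment, protein, config
        )
        total = None
    else:
        label, records, contributions, total = evaluate_contribution(
            ligand, assignment, protein, config
        )
    return SyntheticComplex(
        ligand=ligand,
        assignment=assignment,
        protein=protein,
        rule=config.rule,
        label=label,
        atom_contributions=contributions,
        records=records,
        config=config,
        seed=int(seed),
        total_score=total,
    )


def generate_conditioned(
    ligand: Ligand,
    config: GenerationConfig,
    target_label: str,
    seed: int,
    max_attempts: int = 100,
) -> SyntheticComplex | None:
    """Resample the synthetic protein until the label matches the target.

    Returns the first matching complex, or ``None`` (a discard signal) if no
    attempt out of ``max_attempts`` matched.  The attempt trajectory is a
    pure function of the seed.
    """
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    if target_label not in ("active", "inactive"):
        raise ValueError(f"invalid target label {target_label!r}")
    sub_seeds = np.random.SeedSequence(seed).generate_state(max_attempts) % (2**31 - 1)
    for attempt_seed in sub_seeds:
        cmplx = generate_complex(ligand, config, int(attempt_seed))
        if cmplx.label == target_label:
            return cmplx
    return None


# ---------------------------------------------------------------------------
# Serialization: ligand -> SDF, protein -> PDB (one HETATM pseudo-atom per
# residue), label/contributions/records -> CSV, config -> JSON.


def _protein_to_pdb(protein: SyntheticProtein) -> str:
    lines = []
    for i in range(protein.n_res):
        x, y, z = protein.coords[i]
        resname = _PDB_RESNAME[protein.types[i]]
        lines.append(
            f"HETATM{i + 1:5d}  PS  {resname:>3} A{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f" X"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def _protein_from_pdb(path: str) -> SyntheticProtein:
    coords: list[tuple[float, float, float]] = []
    types: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("HETATM"):
                continue
            try:
                resname = line[17:20].strip()
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                types.append(_PDB_RESNAME_INV[resname])
                coords.append(xyz)
            except (KeyError, ValueError) as exc:
                raise ValueError(f"malformed HETATM at {path}:{lineno}") from exc
    return SyntheticProtein(
        coords=np.array(coords, dtype=float).reshape(-1, 3), types=tuple(types)
    )


def write_complex(cmplx: SyntheticComplex, out_dir: str | os.PathLike) -> dict:
    """Serialize a complex to ``out_dir``; returns the path map."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "ligand": os.path.join(out_dir, "ligand.sdf"),
        "protein": os.path.join(out_dir, "protein.pdb"),
        "labels": os.path.join(out_dir, "labels.csv"),
        "contributions": os.path.join(out_dir, "contributions.csv"),
        "records": os.path.join(out_dir, "records.csv"),
        "config": os.path.join(out_dir, "config.json"),
    }
    write_sdf([cmplx.ligand], paths["ligand"])
    with open(paths["protein"], "w") as fh:
        fh.write(_protein_to_pdb(cmplx.protein))
    pd.DataFrame(
        [
            {
                "complex_id": cmplx.id,
                "label": cmplx.label,
                "total_score": "" if cmplx.total_score is None else cmplx.total_score,
            }
        ]
    ).to_csv(paths["labels"], index=False)
    pd.DataFrame(
        {
            "atom_idx": np.arange(len(cmplx.atom_contributions)),
            "contribution": cmplx.atom_contributions,
        }
    ).to_csv(paths["contributions"], index=False)
    pd.DataFrame(
        [
            {
                "residue_idx": r.residue_idx,
                "atom_idx": r.atom_idx,
                "type": r.kind,
                "distance": r.distance,
                "score": r.score,
            }
            for r in cmplx.records
        ],
        columns=["residue_idx", "atom_idx", "type", "distance", "score"],
    ).to_csv(paths["records"], index=False)
    meta = asdict(cmplx.config)
    meta["seed"] = cmplx.seed
    with open(paths["config"], "w") as fh:
        json.dump(meta, fh, indent=1)
    return paths


def read_complex(paths: dict | str | os.PathLike) -> SyntheticComplex:
    """Invert :func:`write_complex` (up to PDB coordinate rounding)."""
    if not isinstance(paths, dict):
        d = os.fspath(paths)
        paths = {
            "ligand": os.path.join(d, "ligand.sdf"),
            "protein": os.path.join(d, "protein.pdb"),
            "labels": os.path.join(d, "labels.csv"),
            "contributions": os.path.join(d, "contributions.csv"),
            "records": os.path.join(d, "records.csv"),
            "config": os.path.join(d, "config.json"),
        }
    with open(paths["config"]) as fh:
        meta = json.load(fh)
    seed = meta.pop("seed", None)
    config = GenerationConfig(**meta)
    ligand = load_ligands(paths["ligand"], "sdf")[0]
    protein = _protein_from_pdb(paths["protein"])
    labels = pd.read_csv(paths["labels"])
    contributions = pd.read_csv(paths["contributions"])["contribution"].to_numpy(float)
    rec_df = pd.read_csv(paths["records"])
    records = tuple(
        InteractionRecord(
            residue_idx=int(r.residue_idx),
            atom_idx=int(r.atom_idx),
            kind=str(r.type),
            distance=float(r.distance),
            score=float(r.score),
        )
        for r in rec_df.itertuples()
    )
    total = labels.loc[0, "total_score"]
    total = None if pd.isna(total) else float(total)
    return SyntheticComplex(
        ligand=ligand,
        assignment=assign_pharmacophores(ligand, config.rule),
        protein=protein,
        rule=config.rule,
        label=str(labels.loc[0, "label"]),
        atom_contributions=contributions,
        records=records,
        config=config,
        seed=seed,
        total_score=total,
    )
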