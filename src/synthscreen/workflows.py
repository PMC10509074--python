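"""End-to-end reproducible pipelines: dataset builds, benchmarks, case studies.

Every workflow is a pure function of its inputs, configuration and seed:
rerunning with the same arguments reproduces manifests byte for byte.  All
randomness flows from a single integer seed through ``numpy.random``
SeedSequence spawning, and every generated complex records its sub-seed.
"""

from __future__ import annotations

import json
import logging
import os
import platform
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

import synthscreen
from synthscreen.ligand_chem import (
    Ligand,
    generate_fixture_ligands,
    load_ligands,
    similarity_and_size_filter,
)
from synthscreen.synth_generator import (
    GenerationConfig,
    RejectedLigandError,
    SyntheticComplex,
    generate_complex,
    generate_conditioned,
    write_complex,
)
from synthscreen.fingerprints import FeaturizerConfig
from synthscreen.models import (
    TrainedModel,
    build_dataset,
    evaluate_classifier,
    masking_attributions,
    train_random_forest,
)
from synthscreen.attribution_metrics import evaluate_attributions

logger = logging.getLogger(__name__)

DEFAULT_PLEC_CUTOFFS = (2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0)


@dataclass
class BenchmarkSpec:
    """Configuration of the multi-model benchmark."""

    rule: str = "polar"
    ligand_source: str = "fixture"  # "fixture" or a SMILES/SDF path
    n_ligands: int = 2500
    test_size: int = 500
    plec_cutoffs: tuple[float, ...] = DEFAULT_PLEC_CUTOFFS
    include_morgan: bool = True
    n_attribution_eval: int = 100
    seed: int = 0
    generation: GenerationConfig | None = None
    featurizer: FeaturizerConfig = field(default_factory=FeaturizerConfig)
    rf_params: dict | None = None

    def __post_init__(self):
        if self.test_size >= self.n_ligands:
            raise ValueError("test size must be smaller than the dataset size")
        cutoffs = tuple(self.plec_cutoffs)
        if any(c <= 0 for c in cutoffs) or list(cutoffs) != sorted(cutoffs):
            raise ValueError("PLEC cutoffs must be positive and sorted")
        self.plec_cutoffs = cutoffs
        if self.generation is None:
            self.generation = GenerationConfig(rule=self.rule)


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def _resolve_ligands(source: str, n: int, seed: int) -> list[Ligand]:
    if source == "fixture":
        return generate_fixture_ligands(n, seed)
    fmt = "sdf" if source.lower().endswith(".sdf") else "smiles"
    return load_ligands(source, fmt)[:n]


def _provenance(seed: int) -> dict:
    import rdkit
    import sklearn

    return {
        "package": f"synthscreen {synthscreen.__version__}",
        "seed": int(seed),
        "python": platform.python_version(),
        "rdkit": rdkit.__version__,
        "numpy": np.__version__,
        "sklearn": sklearn.__version__,
    }


def build_unconditioned_complexes(
    ligands: list[Ligand], config: GenerationConfig, seed: int
) -> tuple[list[SyntheticComplex], list[str]]:
    """One unconditioned complex per ligand; returns (complexes, rejected ids)."""
    complexes, rejected = [], []
    for lig, s in zip(ligands, _sub_seeds(seed, len(ligands))):
        try:
            complexes.append(generate_complex(lig, config, int(s)))
        except RejectedLigandError:
            rejected.append(lig.id)
    return complexes, rejected


def _bias_diagnostic(complexes: list[SyntheticComplex]) -> pd.DataFrame:
    """Per-label distribution of polar-atom counts (ligand-bias analogue).

    If actives and decoys show near-identical distributions of the number of
    donor/acceptor atoms per ligand, a ligand-only model has no trivial
    handle on the label.
    """
    rows = []
    for cmplx in complexes:
        n_polar = sum(
            1
            for t in cmplx.assignment.atom_types
            if t & {"Donor", "Acceptor"}
        )
        rows.append({"label": cmplx.label, "n_polar_atoms": n_polar})
    df = pd.DataFrame(rows)
    return (
        df.groupby(["label", "n_polar_atoms"])
        .size()
        .rename("count")
        .reset_index()
    )


def run_dataset_build(
    out_dir: str | os.PathLike,
    rule: str = "polar",
    ligand_source: str = "fixture",
    n_ligands: int = 1000,
    seed: int = 0,
    config: GenerationConfig | None = None,
    write_structures: bool = False,
) -> dict:
    """Generate one unconditioned complex per ligand and write a manifest.

    Emits ``manifest.csv`` (complex id, label, total score, sub-seed),
    ``bias_diagnostic.csv`` comparing per-ligand donor/acceptor counts
    between actives and decoys, and ``summary.json``.  With
    ``write_structures=True`` each complex is serialized to its own
    subdirectory.
    """
    config = config or GenerationConfig(rule=rule)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    ligands = _resolve_ligands(ligand_source, n_ligands, seed)
    complexes, rejected = build_unconditioned_complexes(ligands, config, seed)
    manifest = pd.DataFrame(
        {
            "complex_id": [c.id for c in complexes],
            "label": [c.label for c in complexes],
            "total_score": [
                c.total_score if c.total_score is not None else "" for c in complexes
            ],
            "seed": [c.seed for c in complexes],
        }
    )
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    _bias_diagnostic(complexes).to_csv(
        os.path.join(out_dir, "bias_diagnostic.csv"), index=False
    )
    if write_structures:
        for cmplx in complexes:
            write_complex(cmplx, os.path.join(out_dir, cmplx.id))
    summary = {
        "rule": config.rule,
        "n_complexes": len(complexes),
        "n_rejected": len(rejected),
        "rejected_ids": rejected,
        "active_fraction": float(np.mean([c.is_active for c in complexes])),
        "provenance": _provenance(seed),
    }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    summary["complexes"] = complexes
    return summary


def run_bias_matched_build(
    labelled_ligands: list[tuple[Ligand, str]],
    out_dir: str | os.PathLike,
    config: GenerationConfig | None = None,
    seed: int = 0,
    max_attempts: int = 100,
) -> dict:
    """Resample each ligand's protein until the label matches its external one.

    Ligands whose target label is unattainable within ``max_attempts``
    resamplings are discarded; the discard log (ligand id, target label) is
    part of the output.  This reproduces label-conditioned construction from
    externally labelled active/inactive sets, which deliberately injects
    ligand-specific bias into the synthetic dataset.
    """
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    config = config or GenerationConfig()
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    complexes, discards = [], []
    seeds = _sub_seeds(seed, len(labelled_ligands))
    for (lig, target), s in zip(labelled_ligands, seeds):
        try:
            cmplx = generate_conditioned(
                lig, config, target, seed=int(s), max_attempts=max_attempts
            )
        except RejectedLigandError:
            cmplx = None
        if cmplx is None:
            discards.append({"ligand_id": lig.id, "target_label": target})
        else:
            complexes.append(cmplx)
    pd.DataFrame(
        {
            "complex_id": [c.id for c in complexes],
            "label": [c.label for c in complexes],
            "seed": [c.seed for c in complexes],
        }
    ).to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    pd.DataFrame(discards, columns=["ligand_id", "target_label"]).to_csv(
        os.path.join(out_dir, "discards.csv"), index=False
    )
    summary = {
        "n_matched": len(complexes),
        "n_discarded": len(discards),
        "provenance": _provenance(seed),
    }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    summary["complexes"] = complexes
    summary["discards"] = discards
    return summary


def run_active_testset_build(
    ligands: list[Ligand],
    references: list[Ligand],
    out_dir: str | os.PathLike,
    config: GenerationConfig | None = None,
    n: int = 500,
    seed: int = 0,
    max_tanimoto: float = 0.8,
    min_heavy: int = 15,
    max_attempts: int = 100,
) -> dict:
    """Build an all-active external test set with exact ground truth.

    Candidate ligands are filtered against the reference (training) ligands
    (Tanimoto <= ``max_tanimoto``, >= ``min_heavy`` heavy atoms), ``n`` are
    drawn at random, and each synthetic protein is resampled until the
    complex is active.  A contribution-distribution summary (fraction of
    zero-contribution atoms, fractions above scores 1 and 2) is emitted.
    """
    config = config or GenerationConfig()
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    surviving = similarity_and_size_filter(ligands, references, max_tanimoto, min_heavy)
    if len(surviving) < n:
        raise ValueError(
            f"only {len(surviving)} ligands survive filtering; {n} requested "
            f"(shortfall {n - len(surviving)})"
        )
    rng = np.random.default_rng(seed)
    chosen = [surviving[i] for i in rng.choice(len(surviving), size=n, replace=False)]
    complexes = []
    seeds = _sub_seeds(seed + 1, len(chosen))
    for lig, s in zip(chosen, seeds):
        cmplx = generate_conditioned(
            lig, config, "active", seed=int(s), max_attempts=max_attempts
        )
        if cmplx is not None:
            complexes.append(cmplx)
    all_contribs = np.concatenate([c.atom_contributions for c in complexes])
    summary = {
        "rule": config.rule,
        "n_complexes": len(complexes),
        "n_requested": n,
        "fraction_zero_contribution": float((all_contribs == 0).mean()),
        "fraction_above_1": float((all_contribs > 1).mean()),
        "fraction_above_2": float((all_contribs > 2).mean()),
        "provenance": _provenance(seed),
    }
    pd.DataFrame(
        {
            "complex_id": [c.id for c in complexes],
            "label": [c.label for c in complexes],
            "seed": [c.seed for c in complexes],
        }
    ).to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    summary["complexes"] = complexes
    return summary


def _train_eval_one(
    tag: str,
    featurizer: FeaturizerConfig,
    train: list[SyntheticComplex],
    test: list[SyntheticComplex],
    eval_active: list[SyntheticComplex],
    seed: int,
    rf_params: dict | None,
) -> tuple[TrainedModel, dict]:
    X_train, y_train, _ = build_dataset(train, tag, featurizer)
    X_test, y_test, _ = build_dataset(test, tag, featurizer)
    model = train_random_forest(X_train, y_train, tag, featurizer, seed=seed, hyper=rf_params)
    row = {"model": model.name}
    row.update(evaluate_classifier(model, X_test, y_test, seed=seed))
    if eval_active:
        attrs = [
            masking_attributions(model, featurizer, c).scores for c in eval_active
        ]
        report = evaluate_attributions(eval_active, attrs)
        row["attribution_auc"] = report.mean_auc
        row["spearman"] = report.mean_spearman
        row["rer"] = report.rer
    return model, row


def run_benchmark(
    spec: BenchmarkSpec,
    out_dir: str | os.PathLike | None = None,
    complexes: list[SyntheticComplex] | None = None,
) -> dict:
    """Train RF_Morgan and one RF_PLEC per cutoff; evaluate all of them.

    The dataset is split into a seeded random holdout of ``test_size``
    examples and a training remainder.  Classification metrics come from the
    holdout; attribution metrics from a resampled-until-active evaluation set
    derived from the test ligands (ground truth is only meaningful on
    actives).  Returns the results table plus the trained models.
    """
    gen_cfg = spec.generation
    if complexes is None:
        ligands = _resolve_ligands(spec.ligand_source, spec.n_ligands, spec.seed)
        complexes, _ = build_unconditioned_complexes(ligands, gen_cfg, spec.seed)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(complexes))
    test_idx = set(order[: spec.test_size].tolist())
    train = [c for i, c in enumerate(complexes) if i not in test_idx]
    test = [c for i, c in enumerate(complexes) if i in test_idx]
    # attribution evaluation set: test ligands resampled until active
    eval_active: list[SyntheticComplex] = []
    eval_seeds = _sub_seeds(spec.seed + 17, len(test))
    for cmplx, s in zip(test, eval_seeds):
        if len(eval_active) >= spec.n_attribution_eval:
            break
        conditioned = generate_conditioned(
            cmplx.ligand, gen_cfg, "active", seed=int(s), max_attempts=100
        )
        if conditioned is not None:
            eval_active.append(conditioned)
    rows, models = [], {}
    if spec.include_morgan:
        model, row = _train_eval_one(
            "morgan", spec.featurizer, train, test, eval_active, spec.seed, spec.rf_params
        )
        models[model.name] = model
        rows.append(row)
    for cutoff in spec.plec_cutoffs:
        fc = FeaturizerConfig(
            morgan_radius=spec.featurizer.morgan_radius,
            morgan_bits=spec.featurizer.morgan_bits,
            plec_cutoff=cutoff,
            plec_ligand_depth=spec.featurizer.plec_ligand_depth,
            plec_protein_depth=spec.featurizer.plec_protein_depth,
            plec_bits=spec.featurizer.plec_bits,
        )
        model, row = _train_eval_one(
            "plec", fc, train, test, eval_active, spec.seed, spec.rf_params
        )
        models[model.name] = model
        rows.append(row)
    table = pd.DataFrame(rows)
    result = {
        "table": table,
        "models": models,
        "train": train,
        "test": test,
        "eval_active": eval_active,
        "provenance": _provenance(spec.seed),
    }
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "benchmark.csv"), index=False)
        with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
            json.dump(result["provenance"], fh, indent=1)
    return result


def find_single_interaction_complex(
    ligands: list[Ligand],
    config: GenerationConfig,
    seed: int,
    max_tries: int = 2000,
) -> SyntheticComplex:
    """Find a Polar-active complex whose label rests on exactly one pair."""
    seeds = _sub_seeds(seed, max_tries)
    for lig, s in zip(
        (ligands[i % len(ligands)] for i in range(max_tries)), seeds
    ):
        try:
            cmplx = generate_complex(lig, config, int(s))
        except RejectedLigandError:
            continue
        if cmplx.is_active and len(cmplx.records) == 1:
            return cmplx
    raise RuntimeError("no single-interaction active complex found")


def run_perturbation_study(
    base_complex: SyntheticComplex,
    models: dict[str, TrainedModel],
    featurizers: dict[str, FeaturizerConfig],
    distances: np.ndarray | None = None,
    out_path: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """Move the single interacting residue and track the key atom's rank.

    The base complex must be Polar-active through exactly one residue/atom
    pair.  The residue is translated along the residue-atom axis to each
    requested distance; for every perturbed complex and model the masking
    attribution rank (1 = most important, mid-ranks for ties) of the key
    ligand atom is recorded.
    """
    from scipy.stats import rankdata

    if base_complex.rule != "polar" or len(base_complex.records) != 1:
        raise ValueError(
            "base complex must be Polar-active via exactly one interaction"
        )
    if distances is None:
        distances = np.linspace(1.5, 10.0, 50)
    record = base_complex.records[0]
    atom_xyz = base_complex.ligand.coords()[record.atom_idx]
    res_xyz = base_complex.protein.coords[record.residue_idx]
    direction = res_xyz - atom_xyz
    direction = direction / np.linalg.norm(direction)
    rows = []
    for d in distances:
        coords = base_complex.protein.coords.copy()
        coords[record.residue_idx] = atom_xyz + direction * d
        protein = type(base_complex.protein)(
            coords=coords, types=base_complex.protein.types
        )
        perturbed = SyntheticComplex(
            ligand=base_complex.ligand,
            assignment=base_complex.assignment,
            protein=protein,
            rule=base_complex.rule,
            label=base_complex.label,
            atom_contributions=base_complex.atom_contributions,
            records=base_complex.records,
            config=base_complex.config,
            seed=base_complex.seed,
        )
        for name, model in models.items():
            attrs = masking_attributions(model, featurizers[name], perturbed)
            ranks = rankdata(-attrs.scores, method="average")
            rows.append(
                {
                    "model": name,
                    "distance": float(d),
                    "key_atom_rank": float(ranks[record.atom_idx]),
                    "n_atoms": len(attrs.scores),
                }
            )
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(os.fspath(out_path), index=False)
    return df
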