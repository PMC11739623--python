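"""Synthetic-data generators emulating every input table, with known ground truth.

Each generator is deterministic given its rng; :func:`make_fixture` bundles a
named scenario into on-disk CSV/Newick files plus a JSON truth manifest so end
to end runs can be checked by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from dendropy.model import birthdeath

from .design import DesignMatrix, encode_design
from .io import (
    FRACTIONAL_COMPOSITION,
    PRESENCE_ABSENCE,
    BatRecord,
    BiteForceRecord,
    DietMatrix,
    Phylogeny,
    PiperTraitRecord,
    ValidationError,
    write_bat_table,
    write_biteforce_table,
    write_newick,
    write_trait_table,
)

PAPER_SPECIES_COUNTS = {"perspicillata": 84, "sowelli": 111, "castanea": 123}

#: per-species (forearm mm, mass g) means and coefficients of variation
DEFAULT_BAT_TRAITS = {
    "perspicillata": {"forearm_mean": 42.0, "forearm_cv": 0.030, "mass_mean": 19.0, "mass_cv": 0.10},
    "sowelli": {"forearm_mean": 38.5, "forearm_cv": 0.030, "mass_mean": 16.0, "mass_cv": 0.09},
    "castanea": {"forearm_mean": 35.0, "forearm_cv": 0.030, "mass_mean": 12.5, "mass_cv": 0.09},
}

DEFAULT_PLANT_LABELS = [
    "hispidum", "colonense", "silvivagum", "aduncum", "sancti_felicis",
    "peracuminatum", "paulowniifolium", "multiplinervium", "auritum",
    "friedrichsthalii", "reticulatum", "umbellatum", "Type1", "Type2",
    "Type3", "Type4", "Type5", "Type10",
]

DEFAULT_BITEFORCE_TRUTH = {
    "alpha": {"perspicillata": -4.95, "sowelli": -5.05, "castanea": -5.10},
    "beta_sex": 0.10,
    "beta_head": 2.5,
    "sigma_within": 0.05,
    "head_mean": {"perspicillata": 23.0, "sowelli": 21.5, "castanea": 19.5},
    "head_cv": 0.07,
    "head_forearm_corr": 0.76,
}

SCENARIOS = ("null", "strong-species-effect", "forearm-effect", "trait-effect",
             "paper-shaped")


@dataclass
class SyntheticTruth:
    """Ground truth serialized beside every generated dataset."""

    seed: int
    scenario: str
    covariate_labels: list[str]
    plant_labels: list[str]
    b_true: list[list[float]]
    e_true: list[list[float]]
    mode: str
    simplex_renormalize: bool
    biteforce: dict = field(default_factory=dict)
    trait_model: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))

    @property
    def b_array(self) -> np.ndarray:
        return np.asarray(self.b_true)

    @property
    def e_array(self) -> np.ndarray:
        return np.asarray(self.e_true)


def exchangeable_correlation(P: int, rho: float) -> np.ndarray:
    """Valid exchangeable correlation matrix (requires rho > -1/(P-1))."""
    if P > 1 and not (-1.0 / (P - 1) < rho < 1.0):
        raise ValidationError(f"rho={rho} invalid for an exchangeable correlation, P={P}")
    E = np.full((P, P), rho)
    np.fill_diagonal(E, 1.0)
    return E


def simulate_bats(
    n: int = 318,
    species_mix: dict[str, float] | None = None,
    trait_params: dict | None = None,
    n_plants: int = 0,
    rng: np.random.Generator | None = None,
    sex_male_rate: float = 0.5,
    age_rates: tuple[float, float, float] = (0.80, 0.12, 0.08),
    repro_rate: float = 0.30,
    size_correlation: float = 0.7,
) -> list[BatRecord]:
    """Bat cohort without diet: species multinomial, correlated log-normal sizes.

    ``species_mix`` maps species to probabilities (default: the 84/111/123 mix
    over 318).  Occurrence vectors are zero-filled placeholders of length
    ``n_plants`` until a diet is simulated.
    """
    rng = rng or np.random.default_rng()
    if species_mix is None:
        tot = sum(PAPER_SPECIES_COUNTS.values())
        species_mix = {k: v / tot for k, v in PAPER_SPECIES_COUNTS.items()}
    probs = np.array(list(species_mix.values()))
    if not np.isclose(probs.sum(), 1.0):
        raise ValidationError("species mix probabilities must sum to 1")
    names = list(species_mix.keys())
    params = trait_params or DEFAULT_BAT_TRAITS
    sp_draw = rng.choice(len(names), size=n, p=probs)
    records = []
    for i in range(n):
        sp = names[sp_draw[i]]
        p = params[sp]
        mu = np.log([p["forearm_mean"], p["mass_mean"]])
        sds = np.array([p["forearm_cv"], p["mass_cv"]])
        cov = np.array(
            [[sds[0] ** 2, size_correlation * sds[0] * sds[1]],
             [size_correlation * sds[0] * sds[1], sds[1] ** 2]]
        )
        if sds.max() == 0:
            fore, mass = np.exp(mu)
        else:
            fore, mass = np.exp(rng.multivariate_normal(mu, cov, method="cholesky"))
        age = ("adult", "subadult", "juvenile")[rng.choice(3, p=np.asarray(age_rates))]
        records.append(
            BatRecord(
                bat_id=f"bat{i:04d}",
                species=sp,
                sex="male" if rng.random() < sex_male_rate else "female",
                age_class=age,
                repro="reproductive" if rng.random() < repro_rate else "non_reproductive",
                forearm=float(fore),
                mass=float(mass),
                occurrence=np.zeros(n_plants, dtype=np.int8),
            )
        )
    return records


def simulate_diet(
    X: DesignMatrix | np.ndarray,
    B_true: np.ndarray,
    E_true: np.ndarray,
    mode: str,
    rng: np.random.Generator,
    plant_labels: Sequence[str] | None = None,
    simplex_renormalize: bool = True,
) -> DietMatrix:
    """Generate a diet matrix from the latent-Gaussian model W ~ N(XB, E).

    Presence/absence: y = 1[w > 0].  Fractional composition: zeros where
    w <= 0; with ``simplex_renormalize`` the positive parts are renormalized to
    the simplex (rows sum to 1), otherwise y = min(w, 1) which matches the
    fitted model's censoring exactly (used for recovery tests).
    """
    Xm = X.values if isinstance(X, DesignMatrix) else np.asarray(X, float)
    B_true = np.asarray(B_true, float)
    E_true = np.asarray(E_true, float)
    if Xm.shape[1] != B_true.shape[0] or B_true.shape[1] != E_true.shape[0]:
        raise ValidationError("shape mismatch between X, B_true, E_true")
    try:
        L = np.linalg.cholesky(E_true)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("E_true is not positive definite") from exc
    n = Xm.shape[0]
    P = B_true.shape[1]
    labels = list(plant_labels) if plant_labels is not None else [f"plant{p:02d}" for p in range(P)]
    W = Xm @ B_true + rng.standard_normal((n, P)) @ L.T
    if mode == PRESENCE_ABSENCE:
        return DietMatrix((W > 0).astype(float), mode, labels)
    pos = np.clip(W, 0.0, None)
    if simplex_renormalize:
        tot = pos.sum(axis=1, keepdims=True)
        vals = np.divide(pos, tot, out=np.zeros_like(pos), where=tot > 0)
        return DietMatrix(vals, FRACTIONAL_COMPOSITION, labels)
    vals = np.clip(pos, 0.0, 1.0)
    return DietMatrix(vals, FRACTIONAL_COMPOSITION, labels, simplex=False)


def simulate_tree_and_traits(
    P: int,
    birth_rate: float = 1.0,
    trait_sigma: float = 0.4,
    rng: np.random.Generator | None = None,
    labels: Sequence[str] | None = None,
    root_fruit_shape: float = 1.8,
    root_seed_shape: float = 1.3,
) -> tuple[Phylogeny, list[PiperTraitRecord]]:
    """Pure-birth tree scaled to unit height + Brownian-motion shape traits.

    Shape indices evolve as geometric Brownian motion (BM on the log scale,
    exponentiated) so they stay positive; fruit/seed widths are drawn log-normal
    and lengths derived as shape * width.
    """
    if P < 2:
        raise ValidationError("need at least 2 tips")
    rng = rng or np.random.default_rng()
    py_rng = random.Random(int(rng.integers(0, 2**31 - 1)))
    tree = birthdeath.birth_death_tree(
        birth_rate, 0.0, num_extant_tips=P, rng=py_rng, repeat_until_success=True
    )
    labels = list(labels) if labels is not None else [f"plant{p:02d}" for p in range(P)]
    if len(labels) != P:
        raise ValidationError("label count does not match P")
    for leaf, lab in zip(tree.leaf_node_iter(), labels):
        leaf.taxon.label = lab
    # scale to unit height
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    height = max(depths)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / height

    log_traits: dict[int, np.ndarray] = {}
    root_vals = np.log([root_fruit_shape, root_seed_shape])
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            log_traits[id(node)] = root_vals.copy()
        else:
            t = node.edge.length or 0.0
            step = rng.standard_normal(2) * trait_sigma * np.sqrt(t)
            log_traits[id(node)] = log_traits[id(node.parent_node)] + step
    records = []
    for leaf in tree.leaf_node_iter():
        fruit_shape, seed_shape = np.exp(log_traits[id(leaf)])
        fruit_width = float(np.exp(rng.normal(np.log(8.0), 0.2)))
        seed_width = float(np.exp(rng.normal(np.log(0.7), 0.15)))
        records.append(
            PiperTraitRecord(
                plant_species=leaf.taxon.label,
                fruit_length=fruit_shape * fruit_width,
                fruit_width=fruit_width,
                seed_length=seed_shape * seed_width,
                seed_width=seed_width,
            )
        )
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    phylo = Phylogeny.from_newick(newick)
    order = {r.plant_species: r for r in records}
    return phylo, [order[lab] for lab in labels]


def simulate_biteforce(
    n_per_species: int = 10,
    truth: dict | None = None,
    rng: np.random.Generator | None = None,
) -> list[BiteForceRecord]:
    """Bite-force records from the hierarchical allometry with known parameters."""
    rng = rng or np.random.default_rng()
    truth = {**DEFAULT_BITEFORCE_TRUTH, **(truth or {})}
    corr = truth["head_forearm_corr"]
    records = []
    i = 0
    for sp, alpha in truth["alpha"].items():
        head_mu = np.log(truth["head_mean"][sp])
        head_sd = truth["head_cv"]
        fore_mu = np.log(DEFAULT_BAT_TRAITS[sp]["forearm_mean"])
        fore_sd = DEFAULT_BAT_TRAITS[sp]["forearm_cv"]
        cov = np.array(
            [[head_sd**2, corr * head_sd * fore_sd],
             [corr * head_sd * fore_sd, fore_sd**2]]
        )
        for _ in range(n_per_species):
            if head_sd == 0:
                ln_head, ln_fore = head_mu, fore_mu
            else:
                ln_head, ln_fore = rng.multivariate_normal(
                    [head_mu, fore_mu], cov, method="cholesky"
                )
            male = rng.random() < 0.5
            ln_bite = (
                alpha
                + truth["beta_sex"] * male
                + truth["beta_head"] * ln_head
                + rng.normal(0.0, truth["sigma_within"])
            )
            mass = float(np.exp(rng.normal(np.log(DEFAULT_BAT_TRAITS[sp]["mass_mean"]), 0.08)))
            records.append(
                BiteForceRecord(
                    bat_id=f"bf{i:03d}",
                    species=sp,
                    sex="male" if male else "female",
                    head_length=float(np.exp(ln_head)),
                    head_width=float(np.exp(ln_head) * 0.55),
                    head_height=float(np.exp(ln_head) * 0.45),
                    forearm=float(np.exp(ln_fore)),
                    mass=mass,
                    max_bite_force=float(np.exp(ln_bite)),
                )
            )
            i += 1
    return records


# ---------------------------------------------------------------------------
# scenario fixtures
# ---------------------------------------------------------------------------


def _scenario_b_true(
    scenario: str,
    covariate_labels: list[str],
    plant_labels: list[str],
    rng: np.random.Generator,
    fruit_shapes: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    K, P = len(covariate_labels), len(plant_labels)
    B = np.zeros((K, P))
    sp_rows = [covariate_labels.index(s) for s in ("perspicillata", "sowelli", "castanea")]
    B[sp_rows, :] = -0.5  # baseline zero-inflation: ~30% prevalence per cell
    notes: dict = {}
    if scenario == "null":
        pass
    elif scenario == "strong-species-effect":
        # planted values REPLACE the -0.5 baseline so each planted cell's
        # coefficient is clearly nonzero against the flag-vs-zero test
        planted = [(sp_rows[0], 0, 0.7), (sp_rows[0], 1, 0.6), (sp_rows[2], 0, -1.2),
                   (sp_rows[2], 2, -1.1), (sp_rows[1], 3, 0.6)]
        for q, p, v in planted:
            B[q, p] = v
        notes["planted_cells"] = [
            {"covariate": covariate_labels[q], "plant": plant_labels[p], "effect": v}
            for q, p, v in planted
        ]
    elif scenario == "forearm-effect":
        q = covariate_labels.index("forearm")
        planted = [(q, 0, 0.6), (q, 1, 0.5), (q, 2, -0.5)]
        for qq, p, v in planted:
            B[qq, p] = v
        notes["planted_cells"] = [
            {"covariate": "forearm", "plant": plant_labels[p], "effect": v}
            for _, p, v in planted
        ]
    elif scenario == "trait-effect":
        q = covariate_labels.index("forearm")
        z = (fruit_shapes - fruit_shapes.mean()) / fruit_shapes.std()
        B[q, :] = 0.5 * z
        notes["trait_link"] = {"covariate": "forearm", "slope_on_std_fruit_shape": 0.5}
    elif scenario == "paper-shaped":
        for r in sp_rows:
            B[r, :] += rng.uniform(-0.45, 0.45, P)
        B[covariate_labels.index("forearm"), :] = rng.uniform(-0.35, 0.35, P)
        B[covariate_labels.index("mass"), :] = rng.uniform(-0.1, 0.1, P)
        B[covariate_labels.index("age_subadult"), :] = rng.uniform(-0.2, 0.2, P)
        B[covariate_labels.index("age_juvenile"), :] = rng.uniform(-0.2, 0.2, P)
    else:
        raise ValidationError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    return B, notes


def make_fixture(
    name: str,
    seed: int,
    out_dir: str | Path,
    n: int = 318,
    n_plants: int = 18,
    mode: str = PRESENCE_ABSENCE,
    residual_rho: float = 0.3,
) -> SyntheticTruth:
    """Write a complete scenario dataset (four CSVs + Newick + truth manifest).

    Reproducible byte-for-byte at a fixed seed.  Returns the truth object.
    """
    if name not in SCENARIOS:
        raise ValidationError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    plant_labels = (
        DEFAULT_PLANT_LABELS[:n_plants]
        if n_plants <= len(DEFAULT_PLANT_LABELS)
        else [f"plant{p:02d}" for p in range(n_plants)]
    )

    bats = simulate_bats(n=n, n_plants=n_plants, rng=rng)
    X, kept = encode_design(bats)
    assert len(kept) == n  # generator never produces missing covariates
    phylo, traits = simulate_tree_and_traits(
        n_plants, trait_sigma=0.4, rng=rng, labels=plant_labels
    )
    fruit_shapes = np.array([t.fruit_shape_index for t in traits])
    B_true, notes = _scenario_b_true(name, X.column_labels, plant_labels, rng, fruit_shapes)
    E_true = exchangeable_correlation(n_plants, residual_rho)
    diet = simulate_diet(X, B_true, E_true, mode, rng, plant_labels=plant_labels)
    if mode == PRESENCE_ABSENCE:
        for rec, row in zip(bats, diet.values):
            rec.occurrence = row.astype(np.int8)
    bf_truth = dict(DEFAULT_BITEFORCE_TRUTH)
    bf = simulate_biteforce(10, bf_truth, rng)

    write_bat_table(bats, diet, out / "bats.csv")
    write_biteforce_table(bf, out / "biteforce.csv")
    write_trait_table(traits, out / "traits.csv")
    write_newick(phylo, out / "tree.nwk")
    truth = SyntheticTruth(
        seed=seed,
        scenario=name,
        covariate_labels=X.column_labels,
        plant_labels=plant_labels,
        b_true=B_true.tolist(),
        e_true=E_true.tolist(),
        mode=mode,
        simplex_renormalize=True,
        biteforce=bf_truth,
        trait_model={"note": "indices arise through the joint model; see notes"},
        notes=notes,
    )
    truth.to_json(out / "truth.json")
    return truth
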