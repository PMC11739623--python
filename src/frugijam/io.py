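"""Typed readers/writers for the input tables, trees, posterior archives and configs.

All tables are plain delimited text (comma by default) with a required header.
Column names are declared through :class:`ColumnSchema` rather than sniffed, so
deposited field data and synthetic files go through one code path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

BAT_SPECIES = ("perspicillata", "sowelli", "castanea")
SEXES = ("male", "female")
AGE_CLASSES = ("adult", "subadult", "juvenile")
REPRO_LEVELS = ("reproductive", "non_reproductive")

PRESENCE_ABSENCE = "presence_absence"
FRACTIONAL_COMPOSITION = "fractional_composition"

#: float format used for every table we write; round-trips IEEE doubles exactly.
FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """A table violated the declared schema (bad level, duplicate id, bad code)."""


class ValidationError(ValueError):
    """A domain invariant was violated."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class BatRecord:
    """One captured individual: covariates plus the 0/1 plant occurrence vector."""

    bat_id: str
    species: str
    sex: str
    age_class: str
    repro: str
    forearm: float | None
    mass: float | None
    occurrence: np.ndarray

    def __post_init__(self) -> None:
        if self.species not in BAT_SPECIES:
            raise SchemaError(f"unknown bat species {self.species!r}")
        if self.sex not in SEXES:
            raise SchemaError(f"unknown sex {self.sex!r}")
        if self.age_class not in AGE_CLASSES:
            raise SchemaError(f"unknown age class {self.age_class!r}")
        if self.repro not in REPRO_LEVELS:
            raise SchemaError(f"unknown reproductive condition {self.repro!r}")
        for name in ("forearm", "mass"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and positive, got {v!r}")
        self.occurrence = np.asarray(self.occurrence)
        if not np.isin(self.occurrence, (0, 1)).all():
            raise ValidationError(
                f"occurrence vector of bat {self.bat_id!r} has entries outside {{0,1}}"
            )
        self.occurrence = self.occurrence.astype(np.int8)

    @property
    def has_complete_covariates(self) -> bool:
        return self.forearm is not None and self.mass is not None


@dataclass
class DietMatrix:
    """n x P diet matrix, presence/absence or fractional composition.

    ``simplex`` marks fractional matrices whose nonzero rows sum to 1 (true
    compositions, e.g. from equal-weight conversion of presences).  Synthetic
    censored-Tobit responses in [0,1] that are not compositions set it False,
    which relaxes only the row-sum check.
    """

    values: np.ndarray
    mode: str
    species_labels: list[str]
    simplex: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.species_labels = list(self.species_labels)
        if self.values.ndim != 2:
            raise ValidationError("diet matrix must be 2-dimensional")
        if self.values.shape[1] != len(self.species_labels):
            raise ValidationError("column count does not match species_labels")
        if self.mode not in (PRESENCE_ABSENCE, FRACTIONAL_COMPOSITION):
            raise ValidationError(f"unknown diet mode {self.mode!r}")
        if self.mode == PRESENCE_ABSENCE:
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValidationError("presence/absence matrix has entries outside {0,1}")
        else:
            if ((self.values < 0) | (self.values > 1)).any():
                raise ValidationError("fractional values must lie in [0,1]")
            if self.simplex:
                sums = self.values.sum(axis=1)
                ok = np.isclose(sums, 1.0, atol=1e-9) | (sums == 0.0)
                if not ok.all():
                    bad = int(np.flatnonzero(~ok)[0])
                    raise ValidationError(
                        f"fractional row {bad} sums to {sums[bad]:.6f}, expected 1 or 0"
                    )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    @property
    def all_absent_rows(self) -> np.ndarray:
        """Boolean mask of rows with no plant detected."""
        return self.values.sum(axis=1) == 0


@dataclass
class BiteForceRecord:
    """Morphometrics and maximum voluntary bite force for one adult bat."""

    bat_id: str
    species: str
    sex: str
    head_length: float
    head_width: float | None
    head_height: float | None
    forearm: float | None
    mass: float | None
    max_bite_force: float

    def __post_init__(self) -> None:
        if self.species not in BAT_SPECIES:
            raise SchemaError(f"unknown bat species {self.species!r}")
        if self.sex not in SEXES:
            raise SchemaError(f"unknown sex {self.sex!r}")
        if not self.max_bite_force > 0:
            raise ValidationError(f"max_bite_force must be > 0, got {self.max_bite_force}")
        if not self.head_length > 0:
            raise ValidationError(f"head_length must be > 0, got {self.head_length}")


@dataclass
class PiperTraitRecord:
    """Per-plant-species fruit and seed dimensions with derived shape indices.

    The shape index is the ratio of mean length to mean width (ratio of
    averages, computed after averaging replicate measurements).
    """

    plant_species: str
    fruit_length: float
    fruit_width: float
    seed_length: float
    seed_width: float

    def __post_init__(self) -> None:
        for name in ("fruit_length", "fruit_width", "seed_length", "seed_width"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and positive, got {v!r}")

    @property
    def fruit_shape_index(self) -> float:
        return self.fruit_length / self.fruit_width

    @property
    def seed_shape_index(self) -> float:
        return self.seed_length / self.seed_width


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, wrapped around dendropy."""

    newick_string: str
    tree: dendropy.Tree = field(repr=False)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:  # dendropy raises several parse error types
            raise ValidationError(f"cannot parse newick tree: {exc}") from exc
        phylo = cls(newick_string=newick.strip(), tree=tree)
        phylo._validate()
        return phylo

    def _validate(self) -> None:
        labels = self.tip_labels
        if len(labels) == 0:
            raise ValidationError("tree has zero tips")
        if len(set(labels)) != len(labels):
            raise ValidationError("tip labels are not unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def require_tips(self, labels: Iterable[str]) -> None:
        """Raise if any modeled species is missing from the tree."""
        missing = sorted(set(labels) - set(self.tip_labels))
        if missing:
            raise ValidationError(f"species missing from tree: {missing}")


@dataclass
class AnalysisConfig:
    """Run configuration shared by the CLI and the samplers."""

    mode: str = FRACTIONAL_COMPOSITION
    n_iterations: int = 20_000
    n_burnin: int = 4_000
    thin: int = 10
    n_chains: int = 2
    rng_seed: int = 0
    covariates: list[str] = field(
        default_factory=lambda: ["species", "age_class", "sex", "repro", "mass", "forearm"]
    )
    rare_threshold: float = 0.01
    hpd_prob: float = 0.95
    dimension_reduction: str = "none"  # reserved; only full-rank is implemented

    def __post_init__(self) -> None:
        if self.mode not in (PRESENCE_ABSENCE, FRACTIONAL_COMPOSITION):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not self.n_burnin < self.n_iterations:
            raise ValidationError("n_burnin must be < n_iterations")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if not 0 <= self.rare_threshold < 1:
            raise ValidationError("rare_threshold must lie in [0,1)")
        if not 0 < self.hpd_prob < 1:
            raise ValidationError("hpd_prob must lie in (0,1)")
        if self.dimension_reduction != "none":
            raise NotImplementedError("only dimension_reduction='none' is implemented")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# column schemas
# ---------------------------------------------------------------------------


@dataclass
class ColumnSchema:
    """Declares how the bat table's columns map onto :class:`BatRecord` fields.

    ``plant_prefix`` identifies occurrence columns by name prefix;
    ``plant_columns`` overrides with an explicit list.  ``value_maps`` lets raw
    codes (e.g. ``"F"``) be translated to canonical levels before validation.
    """

    bat_id: str = "bat_id"
    species: str = "species"
    sex: str = "sex"
    age_class: str = "age_class"
    repro: str = "repro"
    forearm: str = "forearm_mm"
    mass: str = "mass_g"
    plant_prefix: str = "Piper_"
    plant_columns: list[str] | None = None
    value_maps: dict[str, dict[str, str]] = field(default_factory=dict)

    def plant_cols(self, columns: Sequence[str]) -> list[str]:
        if self.plant_columns is not None:
            missing = [c for c in self.plant_columns if c not in columns]
            if missing:
                raise SchemaError(f"declared plant columns missing from file: {missing}")
            return list(self.plant_columns)
        cols = [c for c in columns if c.startswith(self.plant_prefix)]
        if not cols:
            raise SchemaError(
                f"no occurrence columns found with prefix {self.plant_prefix!r}"
            )
        return cols

    def translate(self, field_name: str, value: str) -> str:
        vmap = self.value_maps.get(field_name)
        if vmap and value in vmap:
            return vmap[value]
        return value


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def read_bat_table(
    path: str | Path,
    schema: ColumnSchema | None = None,
    sep: str = ",",
) -> tuple[list[BatRecord], DietMatrix]:
    """Read a bat-record table; returns records in file order plus the diet matrix.

    Rows with occurrence codes outside {0,1} are rejected with the (0-based,
    header-excluded) row index in the message.  Unknown factor levels and
    duplicate ids raise :class:`SchemaError`.
    """
    schema = schema or ColumnSchema()
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = [schema.bat_id, schema.species, schema.sex, schema.age_class,
                schema.repro, schema.forearm, schema.mass]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"bat table missing required columns: {missing}")
    plant_cols = schema.plant_cols(df.columns)
    labels = [c.removeprefix(schema.plant_prefix) if schema.plant_columns is None else c
              for c in plant_cols]

    records: list[BatRecord] = []
    rows = np.empty((len(df), len(plant_cols)), dtype=np.int8)
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        occ_raw = [row[c] for c in plant_cols]
        try:
            occ = np.array([int(v) for v in occ_raw])
        except ValueError as exc:
            raise SchemaError(f"row {idx}: malformed occurrence value ({exc})") from exc
        if not np.isin(occ, (0, 1)).all():
            bad = occ_raw[int(np.flatnonzero(~np.isin(occ, (0, 1)))[0])]
            raise SchemaError(f"row {idx}: occurrence value {bad!r} not in {{0,1}}")
        bat_id = row[schema.bat_id]
        if bat_id in seen:
            raise SchemaError(f"duplicate bat_id {bat_id!r}")
        seen.add(bat_id)
        try:
            rec = BatRecord(
                bat_id=bat_id,
                species=schema.translate("species", row[schema.species]),
                sex=schema.translate("sex", row[schema.sex]),
                age_class=schema.translate("age_class", row[schema.age_class]),
                repro=schema.translate("repro", row[schema.repro]),
                forearm=_opt_float(row[schema.forearm]),
                mass=_opt_float(row[schema.mass]),
                occurrence=occ,
            )
        except (SchemaError, ValidationError) as exc:
            raise type(exc)(f"row {idx}: {exc}") from exc
        records.append(rec)
        rows[idx] = rec.occurrence
    diet = DietMatrix(rows.astype(float), PRESENCE_ABSENCE, labels)
    return records, diet


def write_bat_table(
    records: Sequence[BatRecord],
    diet: DietMatrix,
    path: str | Path,
    schema: ColumnSchema | None = None,
) -> None:
    schema = schema or ColumnSchema()
    if len(records) != diet.n:
        raise ValidationError("record count does not match diet matrix rows")
    cols = {
        schema.bat_id: [r.bat_id for r in records],
        schema.species: [r.species for r in records],
        schema.sex: [r.sex for r in records],
        schema.age_class: [r.age_class for r in records],
        schema.repro: [r.repro for r in records],
        schema.forearm: [_fmt_opt(r.forearm) for r in records],
        schema.mass: [_fmt_opt(r.mass) for r in records],
    }
    for j, label in enumerate(diet.species_labels):
        cols[f"{schema.plant_prefix}{label}"] = diet.values[:, j].astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)


def _fmt_opt(v: float | None) -> str:
    return "" if v is None else (FLOAT_FMT % v)


_BF_COLUMNS = ["bat_id", "species", "sex", "head_length_mm", "head_width_mm",
               "head_height_mm", "forearm_mm", "mass_g", "max_bite_force_n"]


def read_biteforce_table(path: str | Path, sep: str = ",") -> list[BiteForceRecord]:
    """Read bite-force records; enforces the adult / non-reproductive restriction.

    If the file carries ``age_class`` or ``repro`` columns, any row that is not
    adult and non-reproductive raises — protocol excludes those individuals.
    Head width/height, forearm and mass may be blank (not every individual was
    measured for all of them).
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _BF_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"bite-force table missing columns: {missing}")
    records = []
    for idx, row in df.iterrows():
        if "age_class" in df.columns and row["age_class"] != "adult":
            raise SchemaError(f"row {idx}: bite-force protocol admits adults only")
        if "repro" in df.columns and row["repro"] != "non_reproductive":
            raise SchemaError(
                f"row {idx}: bite-force protocol admits non-reproductive individuals only"
            )
        records.append(
            BiteForceRecord(
                bat_id=row["bat_id"],
                species=row["species"],
                sex=row["sex"],
                head_length=float(row["head_length_mm"]),
                head_width=_opt_float(row["head_width_mm"]),
                head_height=_opt_float(row["head_height_mm"]),
                forearm=_opt_float(row["forearm_mm"]),
                mass=_opt_float(row["mass_g"]),
                max_bite_force=float(row["max_bite_force_n"]),
            )
        )
    return records


def write_biteforce_table(records: Sequence[BiteForceRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "bat_id": [r.bat_id for r in records],
            "species": [r.species for r in records],
            "sex": [r.sex for r in records],
            "head_length_mm": [FLOAT_FMT % r.head_length for r in records],
            "head_width_mm": [_fmt_opt(r.head_width) for r in records],
            "head_height_mm": [_fmt_opt(r.head_height) for r in records],
            "forearm_mm": [_fmt_opt(r.forearm) for r in records],
            "mass_g": [_fmt_opt(r.mass) for r in records],
            "max_bite_force_n": [FLOAT_FMT % r.max_bite_force for r in records],
        }
    )
    df.to_csv(path, index=False)


def biteforce_frame(records: Sequence[BiteForceRecord]) -> pd.DataFrame:
    """Records as a numeric DataFrame for the model-fitting layer."""
    return pd.DataFrame(
        {
            "bat_id": [r.bat_id for r in records],
            "species": [r.species for r in records],
            "sex": [r.sex for r in records],
            "head_length": [r.head_length for r in records],
            "forearm": [np.nan if r.forearm is None else r.forearm for r in records],
            "mass": [np.nan if r.mass is None else r.mass for r in records],
            "max_bite_force": [r.max_bite_force for r in records],
        }
    )


_TRAIT_COLUMNS = ["plant_species", "fruit_length_mm", "fruit_width_mm",
                  "seed_length_mm", "seed_width_mm"]


def read_trait_table(path: str | Path, sep: str = ",") -> list[PiperTraitRecord]:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in _TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trait table missing columns: {missing}")
    if df["plant_species"].duplicated().any():
        dup = df.loc[df["plant_species"].duplicated(), "plant_species"].iloc[0]
        raise SchemaError(f"duplicate plant species {dup!r} in trait table")
    return [
        PiperTraitRecord(
            plant_species=row.plant_species,
            fruit_length=row.fruit_length_mm,
            fruit_width=row.fruit_width_mm,
            seed_length=row.seed_length_mm,
            seed_width=row.seed_width_mm,
        )
        for row in df.itertuples(index=False)
    ]


def write_trait_table(records: Sequence[PiperTraitRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "plant_species": [r.plant_species for r in records],
            "fruit_length_mm": [FLOAT_FMT % r.fruit_length for r in records],
            "fruit_width_mm": [FLOAT_FMT % r.fruit_width for r in records],
            "seed_length_mm": [FLOAT_FMT % r.seed_length for r in records],
            "seed_width_mm": [FLOAT_FMT % r.seed_width for r in records],
        }
    ).to_csv(path, index=False)


def read_newick(path: str | Path) -> Phylogeny:
    """Read a single-tree Newick file (branch lengths required, not ultrametric)."""
    return Phylogeny.from_newick(Path(path).read_text())


def write_newick(phylo: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phylo.newick_string + "\n")


# ---------------------------------------------------------------------------
# posterior archive
# ---------------------------------------------------------------------------


def save_posterior_archive(samples, out_dir: str | Path) -> None:
    """Write posterior draws as per-parameter CSV tables plus a JSON manifest.

    ``samples`` is a :class:`frugijam.gjam.PosteriorSamples`.  Reals are stored
    with 17 significant digits so the round trip is exact; chain/draw indices
    are integers and round-trip bit-exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kxp = [f"{c}|{p}" for c in samples.covariate_labels for p in samples.plant_labels]
    pxp = [f"{a}|{b}" for a in samples.plant_labels for b in samples.plant_labels]
    idx = pd.DataFrame({"chain": samples.chain_ids, "draw": samples.draw_ids})

    def dump(name: str, arr: np.ndarray, columns: list[str]) -> None:
        flat = arr.reshape(arr.shape[0], -1)
        df = pd.concat([idx, pd.DataFrame(flat, columns=columns)], axis=1)
        df.to_csv(out / name, index=False, float_format=FLOAT_FMT)

    dump("b.csv", samples.b, kxp)
    dump("b_cor.csv", samples.b_cor, kxp)
    dump("e.csv", samples.e, pxp)
    dump("sigma.csv", samples.sigma, pxp)
    dump("deviance.csv", samples.deviance[:, None], ["deviance"])
    manifest = {
        "covariate_labels": samples.covariate_labels,
        "plant_labels": samples.plant_labels,
        "mode": samples.mode,
        "seed": samples.seed,
        "n_chains": int(samples.n_chains),
        "chain_length": int(samples.chain_length),
        "dev_at_mean": samples.dev_at_mean,
        "config_hash": samples.config_hash,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_posterior_archive(in_dir: str | Path):
    from .gjam import PosteriorSamples  # local import to avoid a cycle

    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    K = len(manifest["covariate_labels"])
    P = len(manifest["plant_labels"])

    def grab(name: str, shape: tuple[int, ...]) -> tuple[np.ndarray, pd.DataFrame]:
        df = pd.read_csv(src / name, float_precision="round_trip")
        arr = df.drop(columns=["chain", "draw"]).to_numpy()
        return arr.reshape((arr.shape[0],) + shape), df

    b, idx = grab("b.csv", (K, P))
    b_cor, _ = grab("b_cor.csv", (K, P))
    e, _ = grab("e.csv", (P, P))
    sigma, _ = grab("sigma.csv", (P, P))
    dev, _ = grab("deviance.csv", ())
    return PosteriorSamples(
        b=b,
        b_cor=b_cor,
        e=e,
        sigma=sigma,
        deviance=dev.reshape(-1),
        chain_ids=idx["chain"].to_numpy(),
        draw_ids=idx["draw"].to_numpy(),
        covariate_labels=manifest["covariate_labels"],
        plant_labels=manifest["plant_labels"],
        mode=manifest["mode"],
        seed=manifest["seed"],
        dev_at_mean=manifest["dev_at_mean"],
        config_hash=manifest["config_hash"],
    )


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def dump_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
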