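"""Pharmacophore model representation, distance-constraint matching,
activity classification, model evaluation and the screening cascade.

The matcher is purely geometric: a compound matches when some assignment of
typed feature points reproduces every pairwise model distance within the sum
of the two feature radii (the sphere-intersection bound).  For a 3-feature
model this pairwise test is sufficient for hit/miss; RMSD after optimal
rigid superposition is reported per match for ranking.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .chemio_features import (
    FEATURE_TYPES,
    DEFAULT_EMBED_SEED,
    FeaturePointSet,
    MoleculeRecord,
    compute_descriptors,
    ensure_conformer,
    perceive_features,
)
from .errors import ConfigError, DomainError, ModelError, OrientationError

_EMBED_TOL = 1e-9


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelFeature:
    label: str
    feature_type: str
    radius: float

    def __post_init__(self):
        if self.feature_type not in FEATURE_TYPES:
            raise ModelError(f"unknown feature type {self.feature_type!r}")
        if not self.radius > 0:
            raise ModelError(f"feature {self.label!r}: radius must be > 0")


@dataclass(frozen=True)
class PharmacophoreModel:
    """k typed features with tolerance radii and pairwise distances (A)."""

    features: tuple
    distances: tuple  # k x k nested tuple, symmetric, zero diagonal

    def __post_init__(self):
        k = len(self.features)
        if k < 2:
            raise ModelError("a pharmacophore model needs at least 2 features")
        d = self.distance_matrix()
        if d.shape != (k, k):
            raise ModelError(f"distance matrix must be {k}x{k}")
        if not np.allclose(d, d.T, atol=_EMBED_TOL):
            raise ModelError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=_EMBED_TOL):
            raise ModelError("distance matrix must have zero diagonal")
        if np.any(d < 0):
            raise ModelError("distances must be non-negative")

    @property
    def k(self) -> int:
        return len(self.features)

    def distance_matrix(self) -> np.ndarray:
        return np.array(self.distances, dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([f.radius for f in self.features], dtype=float)

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_dict(cls, data: Mapping) -> "PharmacophoreModel":
        feats = tuple(
            ModelFeature(f["label"], f["type"], float(f["radius"]))
            for f in data["features"]
        )
        dist = tuple(tuple(float(x) for x in row) for row in data["distances"])
        return cls(features=feats, distances=dist)

    @classmethod
    def from_yaml(cls, path) -> "PharmacophoreModel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {
            "features": [
                {"label": f.label, "type": f.feature_type, "radius": f.radius}
                for f in self.features
            ],
            "distances": [list(row) for row in self.distances],
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    # -- geometry -----------------------------------------------------------

    def embed(self) -> np.ndarray:
        """Canonical 3-D coordinates reproducing the distance matrix.

        Feature 1 at the origin, feature 2 on +x, feature 3 in the xy
        half-plane (y >= 0).  Raises :class:`ModelError` when the distances
        are infeasible (triangle inequality violated).
        """
        return embed_model(self)


def embed_model(model: PharmacophoreModel) -> np.ndarray:
    d = model.distance_matrix()
    k = model.k
    if k > 3:
        raise ModelError("embedding implemented for k <= 3 features")
    d12 = d[0, 1]
    if d12 <= 0:
        raise ModelError("features 1 and 2 coincide: embedding is degenerate")
    coords = np.zeros((k, 3))
    coords[1, 0] = d12
    if k == 3:
        d13, d23 = d[0, 2], d[1, 2]
        x = (d12 ** 2 + d13 ** 2 - d23 ** 2) / (2.0 * d12)
        y2 = d13 ** 2 - x ** 2
        if y2 < -_EMBED_TOL:
            raise ModelError(
                f"infeasible distance matrix (triangle inequality violated): "
                f"{d12:g}, {d13:g}, {d23:g}"
            )
        coords[2] = [x, float(np.sqrt(max(y2, 0.0))), 0.0]
    # exactness check: the canonical placement must reproduce the matrix
    recomputed = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    if not np.allclose(recomputed, d, atol=1e-9, rtol=0.0):
        raise ModelError("embedding failed to reproduce the distance matrix")
    return coords


def packaged_model() -> PharmacophoreModel:
    """The packaged 3-feature IGF-1R inhibitor model."""
    from importlib.resources import files

    text = files("pharmnet").joinpath("models/igf1r_3pt.yaml").read_text()
    return PharmacophoreModel.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchConfig:
    #: HYD slots also accept HYD_ARO points (an aromatic ring is hydrophobic).
    hyd_accepts_aromatic: bool = True
    #: Multiplier on the pairwise tolerance radius_i + radius_j.
    tolerance_scale: float = 1.0


@dataclass(frozen=True)
class MatchResult:
    matched: bool
    assignment: tuple | None  # point indices, one per model feature
    max_pair_deviation: float
    rmsd: float


def _compatible(slot_type: str, point_type: str, config: MatchConfig) -> bool:
    if slot_type == point_type:
        return True
    if slot_type == "HYD" and point_type == "HYD_ARO":
        return config.hyd_accepts_aromatic
    return False


def match(
    points: FeaturePointSet,
    model: PharmacophoreModel,
    config: MatchConfig = MatchConfig(),
) -> MatchResult:
    """Find the best assignment of feature points onto the model.

    Valid assignments map each model feature to a distinct point of
    compatible type with every pairwise distance within
    ``tolerance_scale * (radius_i + radius_j)`` of the model distance.  The
    assignment minimising the total pairwise deviation wins; ties break
    lexicographically on the point-index tuple.
    """
    k = model.k
    ptypes = points.types()
    n = len(ptypes)
    if n < k:
        return MatchResult(False, None, float("nan"), float("nan"))

    pos = points.positions()
    pdist = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    dmat = model.distance_matrix()
    radii = model.radii()
    tol = config.tolerance_scale * (radii[:, None] + radii[None, :])

    candidates = [
        [i for i in range(n) if _compatible(f.feature_type, ptypes[i], config)]
        for f in model.features
    ]
    if any(not c for c in candidates):
        return MatchResult(False, None, float("nan"), float("nan"))

    pairs = list(itertools.combinations(range(k), 2))
    best: tuple | None = None
    for assign in itertools.product(*candidates):
        if len(set(assign)) != k:
            continue
        devs = [abs(pdist[assign[i], assign[j]] - dmat[i, j]) for i, j in pairs]
        if any(dv > tol[i, j] for dv, (i, j) in zip(devs, pairs)):
            continue
        key = (sum(devs), assign)
        if best is None or key < best[:2]:
            best = (key[0], assign, max(devs))

    if best is None:
        return MatchResult(False, None, float("nan"), float("nan"))
    _, assign, max_dev = best
    rmsd = float("nan")
    if k >= 3:
        rmsd = match_rmsd(pos[list(assign)], model.embed())
    return MatchResult(True, tuple(assign), float(max_dev), rmsd)


def match_rmsd(point_coords: np.ndarray, model_coords: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (proper rotations only).

    Kabsch algorithm with the reflection correction; translation is removed
    by centering, no scaling is applied.
    """
    P = np.asarray(point_coords, dtype=float)
    Q = np.asarray(model_coords, dtype=float)
    if P.shape != Q.shape:
        raise DomainError("point sets must have identical shapes")
    if len(P) < 3:
        raise OrientationError("rigid superposition needs at least 3 points")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    diff = Pc @ R.T - Qc
    return float(np.sqrt((diff ** 2).sum() / len(P)))


# ---------------------------------------------------------------------------
# activity classification
# ---------------------------------------------------------------------------

class ActivityClass(enum.Enum):
    MOST_ACTIVE = "most_active"
    MODERATELY_ACTIVE = "moderately_active"
    LESS_ACTIVE = "less_active"
    INACTIVE = "inactive"


def classify_activity(ic50_uM: float) -> ActivityClass:
    """IC50 thresholds: <=0.5 most, <=20 moderately, <=60 less, >60 inactive.

    Boundaries are inclusive for the more-active class.
    """
    if not ic50_uM > 0:
        raise DomainError(f"IC50 must be positive, got {ic50_uM}")
    if ic50_uM <= 0.5:
        return ActivityClass.MOST_ACTIVE
    if ic50_uM <= 20.0:
        return ActivityClass.MODERATELY_ACTIVE
    if ic50_uM <= 60.0:
        return ActivityClass.LESS_ACTIVE
    return ActivityClass.INACTIVE


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationReport:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def _rate(self, num: int, den: int):
        return num / den if den > 0 else None

    @property
    def sensitivity(self):
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self):
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def accuracy(self):
        return self._rate(self.tp + self.tn, self.total)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def _feature_sets_for(item, embed_seed: int) -> list:
    """Feature sets for one library item (compound-level: any conformer)."""
    if isinstance(item, FeaturePointSet):
        return [item]
    if isinstance(item, MoleculeRecord):
        ensure_conformer(item, seed=embed_seed)
        return [perceive_features(item, ci) for ci in range(len(item.conformers))]
    if isinstance(item, (list, tuple)):
        return list(item)
    raise DomainError(f"cannot extract feature sets from {type(item).__name__}")


def compound_matches(item, model, config=MatchConfig(), embed_seed=DEFAULT_EMBED_SEED) -> bool:
    """A compound is a hit when ANY of its conformers matches the model."""
    return any(
        match(fs, model, config).matched for fs in _feature_sets_for(item, embed_seed)
    )


def evaluate_model(
    model: PharmacophoreModel,
    labeled_library: Sequence,
    config: MatchConfig = MatchConfig(),
    embed_seed: int = DEFAULT_EMBED_SEED,
) -> EvaluationReport:
    """Confusion matrix of the matcher against active/inactive labels.

    ``labeled_library`` holds ``(item, label)`` pairs where ``item`` is a
    :class:`MoleculeRecord`, a :class:`FeaturePointSet` or a list of feature
    sets (one per conformer), and ``label`` is ``"active"``/``"inactive"``.
    """
    if not labeled_library:
        raise DomainError("cannot evaluate a model on an empty library")
    tp = fp = tn = fn = 0
    for item, label in labeled_library:
        if label not in ("active", "inactive"):
            raise DomainError(f"unknown label {label!r}")
        predicted = compound_matches(item, model, config, embed_seed)
        actual = label == "active"
        if predicted and actual:
            tp += 1
        elif predicted and not actual:
            fp += 1
        elif not predicted and actual:
            fn += 1
        else:
            tn += 1
    return EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# screening cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the Lipinski and drug-likeness stages.

    The HBD/HBA comparisons are strict (``<``) by default, matching the
    screening protocol; set ``lipinski_inclusive`` for the canonical
    rule-of-five ``<=``.
    """

    lipinski_inclusive: bool = False
    hbd_max: int = 5
    hba_max: int = 10
    rotatable_max: int = 10
    ring_min: int = 1
    ring_max: int = 6
    tpsa_max: float = 140.0

    @classmethod
    def from_dict(cls, data: Mapping) -> "FilterConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown filter key(s): {sorted(unknown)}")
        return cls(**data)


STAGES = ("pharmacophore", "lipinski", "druglike")


@dataclass(frozen=True)
class StageOutcome:
    passed: bool
    reason: str = ""  # machine-readable, empty when passed


@dataclass
class CompoundScreenResult:
    molecule_id: str
    stages: dict  # stage name -> StageOutcome (stages after a failure absent)

    @property
    def is_hit(self) -> bool:
        return all(
            stage in self.stages and self.stages[stage].passed for stage in STAGES
        )


@dataclass
class ScreeningReport:
    results: list  # of CompoundScreenResult
    stage_survivors: dict  # stage -> count (plus "input")

    @property
    def hits(self) -> list:
        return [r.molecule_id for r in self.results if r.is_hit]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for r in self.results:
            row = {"molecule_id": r.molecule_id, "hit": r.is_hit}
            for stage in STAGES:
                out = r.stages.get(stage)
                row[f"{stage}_pass"] = out.passed if out else None
                row[f"{stage}_reason"] = out.reason if out else ""
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {"stage_survivors": dict(self.stage_survivors), "hits": self.hits}


def screen_library(
    library: Sequence[MoleculeRecord],
    model: PharmacophoreModel,
    filter_config: FilterConfig | Mapping | None = None,
    match_config: MatchConfig = MatchConfig(),
    embed_seed: int = DEFAULT_EMBED_SEED,
) -> ScreeningReport:
    """Run the cascade: pharmacophore match -> Lipinski -> drug-likeness."""
    if not library:
        raise DomainError("cannot screen an empty library")
    if filter_config is None:
        filter_config = FilterConfig()
    elif isinstance(filter_config, Mapping):
        filter_config = FilterConfig.from_dict(filter_config)

    cfg = filter_config
    results = []
    survivors = {"input": len(library), "pharmacophore": 0, "lipinski": 0, "druglike": 0}

    for rec in library:
        stages: dict = {}
        try:
            hit = compound_matches(rec, model, match_config, embed_seed)
            stages["pharmacophore"] = (
                StageOutcome(True) if hit else StageOutcome(False, "no_match")
            )
        except Exception as exc:  # embedding/parsing failures are stage failures
            stages["pharmacophore"] = StageOutcome(False, f"error:{exc}")
        if stages["pharmacophore"].passed:
            survivors["pharmacophore"] += 1
            desc = compute_descriptors(rec)
            reasons = []
            if cfg.lipinski_inclusive:
                if desc.hbd_count > cfg.hbd_max:
                    reasons.append("hbd")
                if desc.hba_count > cfg.hba_max:
                    reasons.append("hba")
            else:
                if desc.hbd_count >= cfg.hbd_max:
                    reasons.append("hbd")
                if desc.hba_count >= cfg.hba_max:
                    reasons.append("hba")
            stages["lipinski"] = (
                StageOutcome(True) if not reasons else StageOutcome(False, ",".join(reasons))
            )
            if stages["lipinski"].passed:
                survivors["lipinski"] += 1
                reasons = []
                if desc.rotatable_bonds > cfg.rotatable_max:
                    reasons.append("rotatable_bonds")
                if not (cfg.ring_min <= desc.ring_count <= cfg.ring_max):
                    reasons.append("rings")
                if desc.tpsa > cfg.tpsa_max:
                    reasons.append("tpsa")
                stages["druglike"] = (
                    StageOutcome(True) if not reasons else StageOutcome(False, ",".join(reasons))
                )
                if stages["druglike"].passed:
                    survivors["druglike"] += 1
        results.append(CompoundScreenResult(rec.id, stages))

    return ScreeningReport(results=results, stage_survivors=survivors)
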