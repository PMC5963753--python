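"""Synthetic inputs with known ground truth.

Provides the curated 23-compound training table and generators for labeled
feature-point libraries: positives are rigid copies of the embedded model
(plus seeded jitter and decoy points), negatives violate at least one
pairwise distance constraint by a wide margin.  Every generated label is
verified against the matcher before the library is returned, so label
soundness holds by construction *and* by check.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .chemio_features import FEATURE_TYPES, FeaturePoint, FeaturePointSet
from .errors import DomainError, GenerationError
from .pharmacophore import (
    ActivityClass,
    MatchConfig,
    PharmacophoreModel,
    classify_activity,
    match,
)

_MAX_TRIES = 200

#: Expected composition of the packaged training table.
TRAINING_SIZE = 23
TRAINING_ACTIVE = 21
TRAINING_INACTIVE = 2
TRAINING_CLASS_COUNTS = {
    ActivityClass.MOST_ACTIVE: 4,
    ActivityClass.MODERATELY_ACTIVE: 13,
    ActivityClass.LESS_ACTIVE: 4,
    ActivityClass.INACTIVE: 2,
}


# ---------------------------------------------------------------------------
# training fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingCompound:
    name: str
    ic50_uM: float
    label: str  # "active" / "inactive"
    activity_class: ActivityClass
    ic50_source: str  # "reported" / "reconstructed"
    reference: str


@dataclass
class TrainingSet:
    rows: list  # of TrainingCompound
    provenance: str = ""

    def validate(self) -> None:
        """Raise :class:`DomainError` unless all composition invariants hold."""
        if len(self.rows) != TRAINING_SIZE:
            raise DomainError(f"training set must have {TRAINING_SIZE} rows, has {len(self.rows)}")
        n_active = sum(1 for r in self.rows if r.label == "active")
        n_inactive = sum(1 for r in self.rows if r.label == "inactive")
        if (n_active, n_inactive) != (TRAINING_ACTIVE, TRAINING_INACTIVE):
            raise DomainError(
                f"training set must have {TRAINING_ACTIVE} active / "
                f"{TRAINING_INACTIVE} inactive rows, has {n_active}/{n_inactive}"
            )
        counts: dict = {}
        for r in self.rows:
            counts[r.activity_class] = counts.get(r.activity_class, 0) + 1
            if not 0.04 <= r.ic50_uM <= 200.0:
                raise DomainError(f"{r.name}: IC50 {r.ic50_uM} outside [0.04, 200] uM")
            if classify_activity(r.ic50_uM) is not r.activity_class:
                raise DomainError(
                    f"{r.name}: stored class {r.activity_class} disagrees with "
                    f"IC50 {r.ic50_uM} uM"
                )
            expected_label = "inactive" if r.activity_class is ActivityClass.INACTIVE else "active"
            if r.label != expected_label:
                raise DomainError(f"{r.name}: label/class mismatch")
        if counts != TRAINING_CLASS_COUNTS:
            raise DomainError(f"class counts {counts} differ from expected")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "name": r.name,
                    "ic50_uM": r.ic50_uM,
                    "label": r.label,
                    "activity_class": r.activity_class.value,
                    "ic50_source": r.ic50_source,
                    "reference": r.reference,
                }
                for r in self.rows
            ]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def training_fixture() -> TrainingSet:
    """The packaged 23-compound training table, validated on load.

    Only picropodophyllin's IC50 is reported verbatim in the source
    narrative; the remaining values were legible only from a figure and are
    flagged ``ic50_source = reconstructed`` (class-consistent by the
    validated invariants).
    """
    from importlib.resources import files

    text = files("pharmnet").joinpath("data/training_set.csv").read_text()
    rows = []
    for rec in csv.DictReader(text.splitlines()):
        rows.append(
            TrainingCompound(
                name=rec["name"],
                ic50_uM=float(rec["ic50_uM"]),
                label=rec["label"],
                activity_class=ActivityClass(rec["activity_class"]),
                ic50_source=rec["ic50_source"],
                reference=rec["reference"],
            )
        )
    ts = TrainingSet(
        rows=rows,
        provenance=(
            "Curated IGF-1R inhibitor training table; IC50 values flagged "
            "'reconstructed' are class-consistent placeholders for values "
            "published only in graphical form."
        ),
    )
    ts.validate()
    return ts


# ---------------------------------------------------------------------------
# synthetic feature-point libraries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticLibrarySpec:
    n_positive: int = 21
    n_negative: int = 2
    jitter_sigma: float = 0.0  # Angstrom
    decoy_points_range: tuple = (0, 0)  # inclusive interval
    seed: int = 0

    def __post_init__(self):
        if self.n_positive < 0 or self.n_negative < 0:
            raise DomainError("compound counts must be >= 0")
        if self.jitter_sigma < 0:
            raise DomainError("jitter_sigma must be >= 0")
        lo, hi = self.decoy_points_range
        if lo < 0 or hi < lo:
            raise DomainError("decoy_points_range must be a non-negative interval")

    def to_dict(self) -> dict:
        return {
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "jitter_sigma": self.jitter_sigma,
            "decoy_points_range": list(self.decoy_points_range),
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _rigid_motion(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    rot = Rotation.random(random_state=rng)
    shift = rng.uniform(-10.0, 10.0, size=3)
    return rot.apply(coords) + shift


def _decoys(
    rng: np.random.Generator, spec: SyntheticLibrarySpec, center: np.ndarray
) -> list:
    lo, hi = spec.decoy_points_range
    count = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    points = []
    for _ in range(count):
        ftype = str(rng.choice(FEATURE_TYPES))
        pos = center + rng.uniform(-5.0, 5.0, size=3)
        points.append(FeaturePoint(ftype, tuple(pos), ()))
    return points


def _feature_set(molecule_id: str, core: np.ndarray, types: Sequence[str], decoys) -> FeaturePointSet:
    points = [
        FeaturePoint(t, tuple(xyz), ()) for t, xyz in zip(types, core)
    ] + list(decoys)
    return FeaturePointSet(molecule_id, 0, points)


def generate_matching_library(
    spec: SyntheticLibrarySpec,
    model: PharmacophoreModel,
    config: MatchConfig = MatchConfig(),
) -> list:
    """Labeled ``(FeaturePointSet, label)`` pairs with guaranteed ground truth.

    Positives: the embedded model under a seeded rigid motion plus isotropic
    Gaussian jitter, rejected and resampled while the jittered points no
    longer match.  Negatives: a core triple scaled so that every pairwise
    distance violates its tolerance by at least twice the tolerance, then
    verified not to match (decoys could otherwise recreate a valid triple).
    """
    rng = np.random.default_rng(spec.seed)
    base = model.embed()
    types = [f.feature_type for f in model.features]
    radii = model.radii()
    d = model.distance_matrix()

    library = []
    attempts = 0
    accepted = 0
    for i in range(spec.n_positive):
        for _try in range(_MAX_TRIES):
            attempts += 1
            core = _rigid_motion(base, rng)
            core = core + rng.normal(0.0, spec.jitter_sigma, size=core.shape)
            fs = _feature_set(f"pos-{i:03d}", core, types, _decoys(rng, spec, core.mean(axis=0)))
            if match(fs, model, config).matched:
                accepted += 1
                library.append((fs, "active"))
                break
        else:
            raise GenerationError(
                f"positive {i}: rejection rate exceeded {_MAX_TRIES} tries "
                f"(jitter_sigma={spec.jitter_sigma} too large for the model tolerances)"
            )

    # scale factor pushing every pairwise distance out of its band by >= 2x
    # the tolerance (violation margin 2*(r_i+r_j) beyond the r_i+r_j band)
    scale = 1.0
    for a in range(model.k):
        for b in range(a + 1, model.k):
            tol = config.tolerance_scale * (radii[a] + radii[b])
            scale = max(scale, 1.0 + 3.0 * tol / d[a, b])
    for i in range(spec.n_negative):
        for _try in range(_MAX_TRIES):
            core = _rigid_motion(base * scale, rng)
            fs = _feature_set(f"neg-{i:03d}", core, types, _decoys(rng, spec, core.mean(axis=0)))
            if not match(fs, model, config).matched:
                library.append((fs, "inactive"))
                break
        else:
            raise GenerationError(
                f"negative {i}: decoy points kept recreating a match after "
                f"{_MAX_TRIES} tries; reduce decoy_points_range"
            )

    # verification pass: ground truth must agree with the matcher
    for fs, label in library:
        assert (label == "active") == match(fs, model, config).matched
    return library


def generate_random_feature_sets(n: int, points_per_set: int, seed: int) -> list:
    """Seeded uniform feature sets in a 10 A box (matcher-oracle fodder)."""
    if n < 0 or points_per_set < 0:
        raise DomainError("n and points_per_set must be >= 0")
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n):
        points = [
            FeaturePoint(
                str(rng.choice(FEATURE_TYPES)),
                tuple(rng.uniform(0.0, 10.0, size=3)),
                (),
            )
            for _ in range(points_per_set)
        ]
        sets.append(FeaturePointSet(f"rand-{i:04d}", 0, points))
    return sets


# ---------------------------------------------------------------------------
# feature-library round trip (CSV)
# ---------------------------------------------------------------------------

_LIB_COLUMNS = ["set_id", "label", "point_index", "feature_type", "x", "y", "z"]


def write_feature_library(library, path) -> None:
    """Write ``(FeaturePointSet, label)`` pairs as a flat CSV."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LIB_COLUMNS)
        for fs, label in library:
            for k, p in enumerate(fs.points):
                writer.writerow(
                    [fs.molecule_id, label, k, p.feature_type, *[repr(float(v)) for v in p.position]]
                )


def read_feature_library(path) -> list:
    """Inverse of :func:`write_feature_library`."""
    groups: dict = {}
    order = []
    with Path(path).open() as fh:
        for rec in csv.DictReader(fh):
            key = (rec["set_id"], rec["label"])
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(
                FeaturePoint(
                    rec["feature_type"],
                    (float(rec["x"]), float(rec["y"]), float(rec["z"])),
                    (),
                )
            )
    return [
        (FeaturePointSet(set_id, 0, points), label)
        for (set_id, label), points in ((k, groups[k]) for k in order)
    ]
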