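"""Numeric encoding of descriptor vectors into design matrices.

Two encodings are supported:

* ``"ann"`` — one indicator node per categorical level (a five-level metal
  gives five 0/1 columns) and z-scored continuous columns; this is the
  network input layer convention, 27 nodes for descriptor set g.
* ``"lasso"`` — reference-level binary coding (Co is the all-zeros metal
  reference, O the connecting-atom reference) suitable for linear models
  where a full one-hot block would be collinear with the intercept.

Normalization statistics and level maps are frozen at fit time in an
:class:`EncodingMeta`; applying the meta to new data always re-uses the
training statistics, and unseen categorical levels raise, directing the
caller to the reliability tooling rather than silently extrapolating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .descriptors import CONNECTING_ATOM_LEVELS, DescriptorVector

__all__ = ["EncodingMeta", "OutOfVocabularyError", "fit_encoding", "apply_encoding", "encode"]

#: Fixed level order for categoricals with a known domain.
_KNOWN_LEVELS = {
    "metal": ("Cr", "Mn", "Fe", "Co", "Ni"),
    "L_eq": CONNECTING_ATOM_LEVELS,
    "L_ax": CONNECTING_ATOM_LEVELS,
}

#: Reference level dropped in the lasso encoding.
_REFERENCE_LEVEL = {"metal": "Co", "L_eq": "O", "L_ax": "O"}


class OutOfVocabularyError(ValueError):
    """A categorical level absent from the fitted encoding was encountered."""


@dataclass
class EncodingMeta:
    """Frozen encoding recipe: level maps plus training mean/std per column."""

    mode: str
    set_id: str
    feature_names: tuple[str, ...]
    categorical: tuple[str, ...]
    levels: dict[str, tuple[str, ...]]
    reference: dict[str, str] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    stds: dict[str, float] = field(default_factory=dict)

    @property
    def column_names(self) -> list[str]:
        cols: list[str] = []
        for name in self.feature_names:
            if name in self.categorical:
                for level in self.levels[name]:
                    if self.mode == "lasso" and level == self.reference.get(name):
                        continue
                    cols.append(f"{name}={level}")
            else:
                cols.append(name)
        return cols

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "set_id": self.set_id,
            "feature_names": list(self.feature_names),
            "categorical": list(self.categorical),
            "levels": {k: list(v) for k, v in self.levels.items()},
            "reference": dict(self.reference),
            "means": dict(self.means),
            "stds": dict(self.stds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingMeta":
        return cls(
            mode=d["mode"],
            set_id=d["set_id"],
            feature_names=tuple(d["feature_names"]),
            categorical=tuple(d["categorical"]),
            levels={k: tuple(v) for k, v in d["levels"].items()},
            reference=dict(d["reference"]),
            means={k: float(v) for k, v in d["means"].items()},
            stds={k: float(v) for k, v in d["stds"].items()},
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "EncodingMeta":
        return cls.from_dict(json.loads(s))


def _check_consistent(vectors: Sequence[DescriptorVector]) -> None:
    if not vectors:
        raise ValueError("cannot encode an empty list of descriptor vectors")
    names = vectors[0].names
    set_id = vectors[0].set_id
    for v in vectors[1:]:
        if v.set_id != set_id or v.names != names:
            raise ValueError("descriptor vectors have inconsistent sets or columns")


def fit_encoding(vectors: Sequence[DescriptorVector], mode: str = "ann") -> EncodingMeta:
    """Learn level maps and normalization statistics from training vectors."""
    if mode not in ("ann", "lasso"):
        raise ValueError(f"mode must be 'ann' or 'lasso', got {mode!r}")
    _check_consistent(vectors)
    first = vectors[0]
    levels: dict[str, tuple[str, ...]] = {}
    reference: dict[str, str] = {}
    for name in first.categorical:
        if name in _KNOWN_LEVELS:
            levels[name] = _KNOWN_LEVELS[name]
        elif name in ("lig_eq", "lig_ax"):
            # full-ligand-identity coding (set a): the level domain is the
            # bundled library, extended by any user ligands present
            from .ligands import load_ligand_library

            known = list(load_ligand_library())
            extras = sorted({str(v.values[name]) for v in vectors} - set(known))
            levels[name] = tuple(known + extras)
        else:
            observed = sorted({str(v.values[name]) for v in vectors})
            levels[name] = tuple(observed)
        if mode == "lasso":
            reference[name] = _REFERENCE_LEVEL.get(name, levels[name][0])
    means: dict[str, float] = {}
    stds: dict[str, float] = {}
    for name in first.names:
        if name in first.categorical:
            continue
        col = np.array([float(v.values[name]) for v in vectors])
        mu = float(col.mean())
        sd = float(col.std(ddof=0))
        # zero-variance guard (with floating-point slack): a constant column
        # maps to exactly 0
        if sd <= 1e-12 * max(1.0, abs(mu)):
            mu, sd = float(col[0]), 1.0
        means[name] = mu
        stds[name] = sd
    return EncodingMeta(
        mode=mode,
        set_id=first.set_id,
        feature_names=first.names,
        categorical=first.categorical,
        levels=levels,
        reference=reference,
        means=means,
        stds=stds,
    )


def apply_encoding(vectors: Sequence[DescriptorVector], meta: EncodingMeta) -> np.ndarray:
    """Encode vectors with a previously fitted meta (training statistics only)."""
    _check_consistent(vectors)
    if vectors[0].set_id != meta.set_id or vectors[0].names != meta.feature_names:
        raise ValueError(
            f"descriptor vectors (set {vectors[0].set_id}) do not match the "
            f"encoding meta (set {meta.set_id})"
        )
    rows = np.empty((len(vectors), meta.n_columns))
    for r, vec in enumerate(vectors):
        out: list[float] = []
        for name in meta.feature_names:
            val = vec.values[name]
            if name in meta.categorical:
                level = str(val)
                if level not in meta.levels[name]:
                    raise OutOfVocabularyError(
                        f"level {level!r} of {name!r} was not seen at encoding time "
                        f"(known: {meta.levels[name]}); the complex lies outside the "
                        "model vocabulary — consult the descriptor-distance reliability check"
                    )
                for lv in meta.levels[name]:
                    if meta.mode == "lasso" and lv == meta.reference.get(name):
                        continue
                    out.append(1.0 if lv == level else 0.0)
            else:
                out.append((float(val) - meta.means[name]) / meta.stds[name])
        rows[r] = out
    return rows


def encode(
    vectors: Sequence[DescriptorVector], mode: str = "ann"
) -> tuple[np.ndarray, EncodingMeta]:
    """Fit an encoding on ``vectors`` and return the design matrix and meta."""
    meta = fit_encoding(vectors, mode=mode)
    return apply_encoding(vectors, meta), meta
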