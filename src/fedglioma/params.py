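"""Ordered collections of named parameter arrays with vector-space algebra.

Federated aggregation treats a whole network as a single flat vector: central
updates average client weights, the dynamic-regularization accumulator is a
running sum of weight differences, and the gradient-correction state is shaped
exactly like the weights.  ``ParameterSet`` gives all of these one container
that supports ``u + v``, ``c * u``, ``dot``, ``norm`` and lossless HDF5
round-tripping.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from collections.abc import Iterator, Mapping

import h5py
import numpy as np

__all__ = ["ParameterSet"]


def _as_float(arr) -> np.ndarray:
    """Coerce to a float array, keeping float32 when already float32
    (training runs in single precision; gradient checks in double)."""
    arr = np.asarray(arr)
    if arr.dtype == np.float32:
        return arr
    return arr.astype(np.float64, copy=False)


class ParameterSet(Mapping):
    """Immutable-keyed, ordered mapping ``name -> ndarray`` with linear algebra.

    All binary operations require operands with identical keys and shapes;
    a mismatch raises ``ValueError`` rather than broadcasting silently.
    """

    def __init__(self, arrays: Mapping[str, np.ndarray] | None = None):
        self._arrays: OrderedDict[str, np.ndarray] = OrderedDict()
        if arrays is not None:
            for name, arr in arrays.items():
                self._arrays[name] = _as_float(arr)

    # -- Mapping interface -------------------------------------------------
    def __getitem__(self, name: str) -> np.ndarray:
        return self._arrays[name]

    def __setitem__(self, name: str, value: np.ndarray) -> None:
        self._arrays[name] = _as_float(value)

    @property
    def dtype(self):
        return next(iter(self._arrays.values())).dtype

    def astype(self, dtype) -> "ParameterSet":
        return ParameterSet({k: v.astype(dtype) for k, v in
                             self._arrays.items()})

    def __iter__(self) -> Iterator[str]:
        return iter(self._arrays)

    def __len__(self) -> int:
        return len(self._arrays)

    def keys(self):
        return self._arrays.keys()

    # -- structure ---------------------------------------------------------
    def _check_compatible(self, other: "ParameterSet") -> None:
        if list(self.keys()) != list(other.keys()):
            raise ValueError("parameter sets have different keys")
        for k in self:
            if self[k].shape != other[k].shape:
                raise ValueError(f"shape mismatch for {k!r}: "
                                 f"{self[k].shape} vs {other[k].shape}")

    @property
    def n_parameters(self) -> int:
        return int(sum(a.size for a in self._arrays.values()))

    def copy(self) -> "ParameterSet":
        return ParameterSet({k: v.copy() for k, v in self._arrays.items()})

    def zeros_like(self) -> "ParameterSet":
        return ParameterSet({k: np.zeros_like(v) for k, v in self._arrays.items()})

    # -- algebra -----------------------------------------------------------
    def __add__(self, other: "ParameterSet") -> "ParameterSet":
        self._check_compatible(other)
        return ParameterSet({k: self[k] + other[k] for k in self})

    def __sub__(self, other: "ParameterSet") -> "ParameterSet":
        self._check_compatible(other)
        return ParameterSet({k: self[k] - other[k] for k in self})

    def __mul__(self, c: float) -> "ParameterSet":
        c = float(c)
        return ParameterSet({k: c * self[k] for k in self})

    __rmul__ = __mul__

    def __truediv__(self, c: float) -> "ParameterSet":
        return self * (1.0 / float(c))

    def __neg__(self) -> "ParameterSet":
        return self * -1.0

    def dot(self, other: "ParameterSet") -> float:
        self._check_compatible(other)
        return float(sum(np.vdot(self[k], other[k]) for k in self))

    def norm(self) -> float:
        """Euclidean norm of the flattened parameter vector."""
        return float(np.sqrt(sum(float(np.vdot(a, a))
                                 for a in self._arrays.values())))

    def allclose(self, other: "ParameterSet", rtol=1e-12, atol=1e-12) -> bool:
        self._check_compatible(other)
        return all(np.allclose(self[k], other[k], rtol=rtol, atol=atol)
                   for k in self)

    def equal(self, other: "ParameterSet") -> bool:
        """Bitwise equality of every array."""
        self._check_compatible(other)
        return all(np.array_equal(self[k], other[k]) for k in self)

    @staticmethod
    def mean(sets: list["ParameterSet"],
             weights: list[float] | None = None) -> "ParameterSet":
        """(Weighted) mean of several parameter sets."""
        if not sets:
            raise ValueError("mean of empty list of parameter sets")
        if weights is None:
            weights = [1.0 / len(sets)] * len(sets)
        else:
            if len(weights) != len(sets):
                raise ValueError("weights and sets length mismatch")
            total = float(sum(weights))
            weights = [w / total for w in weights]
        out = sets[0] * weights[0]
        for w, s in zip(weights[1:], sets[1:]):
            out = out + s * w
        return out

    # -- serialization -----------------------------------------------------
    def to_hdf5(self, path, header: dict | None = None) -> None:
        """Write arrays (and an optional JSON header) to an HDF5 checkpoint."""
        with h5py.File(path, "w") as f:
            f.attrs["order"] = json.dumps(list(self.keys()))
            if header is not None:
                f.attrs["header"] = json.dumps(header)
            g = f.create_group("params")
            for k, v in self._arrays.items():
                g.create_dataset(k, data=v)

    @classmethod
    def from_hdf5(cls, path) -> tuple["ParameterSet", dict | None]:
        with h5py.File(path, "r") as f:
            order = json.loads(f.attrs["order"])
            header = json.loads(f.attrs["header"]) if "header" in f.attrs else None
            arrays = OrderedDict((k, f["params"][k][()]) for k in order)
        return cls(arrays), header

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"ParameterSet({len(self)} arrays, "
                f"{self.n_parameters} parameters)")
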