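"""Shared state containers, seeded RNG streams, config handling and snapshot I/O.

The three simulators in this package share a small set of in-memory states:

``CellLattice``
    A discrete W x H grid with entries +1 (strain A, "red"), -1 (strain B,
    "blue") and 0 (empty patch), used by the individual-based killing model.
``SpinLattice``
    A W x H grid of +/-1 spins with no empty state, used by the Ising model.
``FieldState``
    Continuous non-negative density fields A and B (and optionally a public
    good concentration S) on a regular periodic grid, used by the
    reaction-diffusion model.

Discrete snapshots are written both as an indexed PNG (for visualisation)
and as a whitespace-delimited integer text grid, which is the authoritative
lossless form; continuous fields are written as one CSV per field.  Every
snapshot carries a JSON sidecar with step/time, seed and provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "CellLattice",
    "SpinLattice",
    "FieldState",
    "RunConfig",
    "make_rng",
    "read_label_image",
    "write_snapshot",
    "read_snapshot",
    "load_grid",
]

# Palette used for indexed-PNG snapshots of cell lattices.  Index order is
# fixed so that PNG round trips are deterministic: 0 -> empty, 1 -> +1, 2 -> -1.
_LABEL_TO_INDEX = {0: 0, 1: 1, -1: 2}
_INDEX_TO_LABEL = {v: k for k, v in _LABEL_TO_INDEX.items()}
_PALETTE = [0, 0, 0, 205, 45, 45, 45, 75, 205]  # black, red, blue


def _validate_labels(grid: np.ndarray, allowed: tuple[int, ...]) -> None:
    bad = np.setdiff1d(np.unique(grid), np.asarray(allowed))
    if bad.size:
        raise ValueError(f"invalid lattice entries {bad.tolist()}; allowed {list(allowed)}")


@dataclass
class CellLattice:
    """Discrete two-strain lattice: +1 strain A, -1 strain B, 0 empty."""

    grid: np.ndarray
    step: int = 0
    seed: int = 0
    boundary: str = "closed"  # "closed" or "periodic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2:
            raise ValueError("CellLattice grid must be 2-D")
        _validate_labels(self.grid, (-1, 0, 1))
        if self.boundary not in ("closed", "periodic"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        if self.step < 0:
            raise ValueError("step must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def counts(self) -> dict[str, int]:
        """Counts of strain A, strain B and empty sites."""
        g = self.grid
        return {
            "n_A": int(np.count_nonzero(g == 1)),
            "n_B": int(np.count_nonzero(g == -1)),
            "n_empty": int(np.count_nonzero(g == 0)),
        }


@dataclass
class SpinLattice:
    """Ising spin lattice: entries strictly in {+1, -1}."""

    spins: np.ndarray
    sweep: int = 0
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spins = np.asarray(self.spins, dtype=np.int8)
        if self.spins.ndim != 2:
            raise ValueError("SpinLattice spins must be 2-D")
        _validate_labels(self.spins, (-1, 1))
        if self.sweep < 0:
            raise ValueError("sweep must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.spins.shape

    def magnetization(self) -> float:
        return float(self.spins.mean())


@dataclass
class FieldState:
    """Continuous density fields on a periodic grid (1-D or 2-D).

    ``A`` and ``B`` are strain densities; ``S`` is the optional public-good
    concentration.  All fields share one shape; ``dx`` is the grid spacing
    and ``t`` the simulation time.
    """

    A: np.ndarray
    B: np.ndarray
    S: np.ndarray | None = None
    dx: float = 1.0
    t: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        self.B = np.asarray(self.B, dtype=np.float64)
        if self.A.shape != self.B.shape:
            raise ValueError("A and B fields must share one shape")
        if self.S is not None:
            self.S = np.asarray(self.S, dtype=np.float64)
            if self.S.shape != self.A.shape:
                raise ValueError("S field must share the shape of A and B")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        for name in ("A", "B", "S"):
            f = getattr(self, name)
            if f is not None and np.any(f < 0):
                raise ValueError(f"field {name} has negative entries")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.A.shape

    def composition(self) -> np.ndarray:
        """Volume fraction phi_A = A / (A + B); NaN where both vanish."""
        total = self.A + self.B
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.A / total, np.nan)

    def copy(self) -> "FieldState":
        return FieldState(
            A=self.A.copy(),
            B=self.B.copy(),
            S=None if self.S is None else self.S.copy(),
            dx=self.dx,
            t=self.t,
            meta=dict(self.meta),
        )


@dataclass
class RunConfig:
    """Declarative description of one simulation run.

    ``record`` is a strictly increasing list of steps (discrete models) or
    times (continuous models) at which snapshots are taken.  Seeds are always
    explicit; there is no silent wall-clock seeding anywhere in the package.
    """

    model: str  # ibm | ising | pde | pde_public_goods | ode
    params: dict = field(default_factory=dict)
    n_steps: int | None = None
    t_end: float | None = None
    record: Sequence[float] = field(default_factory=list)
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("ibm", "ising", "pde", "pde_public_goods", "ode"):
            raise ValueError(f"unknown model {self.model!r}")
        rec = list(self.record)
        if any(b <= a for a, b in zip(rec, rec[1:])):
            raise ValueError("record schedule must be strictly increasing")
        if self.seed is None:
            raise ValueError("seed must be explicit")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def params_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def make_rng(seed: int, stream: str = "") -> np.random.Generator:
    """Return an independent, reproducible random stream for (seed, stream).

    One master seed spawns labelled substreams, one per module, so that e.g.
    the lattice initialisation and the per-step update draws are decoupled:
    adding draws to one stream never perturbs another.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")
    key = zlib.crc32(stream.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))


def _parse_text_grid(path: Path) -> np.ndarray:
    rows: list[list[int]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        rows.append([int(tok) for tok in line.split()])
    if not rows:
        raise ValueError(f"empty text grid: {path}")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"non-rectangular text grid: {path}")
    return np.array(rows, dtype=np.int64)


def read_label_image(
    path: str | Path,
    mapping: Mapping[int, int] | None = None,
    boundary: str = "closed",
) -> CellLattice:
    """Read a two-genotype label image (8-bit PNG or integer text grid).

    ``mapping`` takes every distinct pixel/cell value to a lattice label in
    {+1, -1, 0} and must cover all values present; an unmapped value raises
    with the offending value named.  If omitted, the identity mapping on
    {-1, 0, 1} is used for text grids and the package's own palette-index
    mapping for PNGs written by :func:`write_snapshot`.
    """
    path = Path(path)
    if path.suffix.lower() == ".png":
        raw = np.asarray(Image.open(path), dtype=np.int64)
        if raw.ndim == 3:  # RGB(A): collapse identical channels, else refuse
            if not (raw[..., :3] == raw[..., :1]).all():
                raise ValueError(f"{path}: colour PNG is not a label image")
            raw = raw[..., 0]
        default = dict(_INDEX_TO_LABEL)
    else:
        raw = _parse_text_grid(path)
        default = {-1: -1, 0: 0, 1: 1}
    mapping = dict(mapping) if mapping is not None else default
    out = np.zeros(raw.shape, dtype=np.int8)
    seen = np.unique(raw)
    for v in seen:
        if int(v) not in mapping:
            raise ValueError(f"unmapped label {int(v)} in {path}")
        out[raw == v] = mapping[int(v)]
    return CellLattice(
        grid=out,
        boundary=boundary,
        meta={"source": str(path), "mapping": {int(k): int(v) for k, v in mapping.items()}},
    )


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_snapshot(state: CellLattice | SpinLattice | FieldState, path: str | Path) -> list[Path]:
    """Write a state snapshot; returns the list of files written.

    ``path`` is a base name (any extension is stripped): discrete lattices
    produce ``base.txt`` (authoritative), ``base.png`` and ``base.json``;
    continuous fields produce one ``base.<field>.csv`` per field plus the
    JSON sidecar.
    """
    base = Path(path)
    if base.suffix:
        base = base.with_suffix("")
    base.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        if isinstance(state, (CellLattice, SpinLattice)):
            grid = state.grid if isinstance(state, CellLattice) else state.spins
            txt = base.with_suffix(".txt")
            np.savetxt(txt, grid, fmt="%d")
            written.append(txt)
            idx = np.zeros(grid.shape, dtype=np.uint8)
            for label, index in _LABEL_TO_INDEX.items():
                idx[grid == label] = index
            img = Image.fromarray(idx, mode="P")
            img.putpalette(_PALETTE)
            png = base.with_suffix(".png")
            img.save(png)
            written.append(png)
            meta = {
                "kind": "cells" if isinstance(state, CellLattice) else "spins",
                "step": int(state.step if isinstance(state, CellLattice) else state.sweep),
                "seed": int(state.seed),
                "shape": list(grid.shape),
                "palette_index_to_label": {str(i): l for l, i in _LABEL_TO_INDEX.items()},
            }
            if isinstance(state, CellLattice):
                meta["boundary"] = state.boundary
        else:
            meta = {
                "kind": "fields",
                "t": float(state.t),
                "dx": float(state.dx),
                "shape": list(state.shape),
                "fields": [],
            }
            for name in ("A", "B", "S"):
                f = getattr(state, name)
                if f is None:
                    continue
                csv = base.parent / f"{base.name}.{name}.csv"
                np.savetxt(csv, np.atleast_2d(f), delimiter=",")
                written.append(csv)
                meta["fields"].append(name)
        _sidecar(base).write_text(json.dumps(meta, indent=1))
        written.append(_sidecar(base))
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed writing snapshot at {base}: {exc}") from exc
    return written


def read_snapshot(path: str | Path) -> CellLattice | SpinLattice | FieldState:
    """Read a snapshot written by :func:`write_snapshot` (text is authoritative)."""
    base = Path(path)
    if base.suffix:
        base = base.with_suffix("")
    meta = json.loads(_sidecar(base).read_text())
    if meta["kind"] in ("cells", "spins"):
        grid = _parse_text_grid(base.with_suffix(".txt"))
        if meta["kind"] == "cells":
            return CellLattice(
                grid=grid.astype(np.int8),
                step=meta["step"],
                seed=meta["seed"],
                boundary=meta.get("boundary", "closed"),
            )
        return SpinLattice(spins=grid.astype(np.int8), sweep=meta["step"], seed=meta["seed"])
    fields = {}
    for name in meta["fields"]:
        arr = np.loadtxt(base.parent / f"{base.name}.{name}.csv", delimiter=",", ndmin=2)
        if len(meta["shape"]) == 1:
            arr = arr.ravel()
        fields[name] = arr
    return FieldState(
        A=fields["A"], B=fields["B"], S=fields.get("S"), dx=meta["dx"], t=meta["t"]
    )


def load_grid(path: str | Path, mapping: Mapping[int, int] | None = None) -> np.ndarray:
    """Convenience: read a label image/text grid and return its bare array."""
    return read_label_image(path, mapping=mapping).grid
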