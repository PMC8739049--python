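"""Foci datasets and Sleuth-style text I/O.

A *focus* is one reported peak coordinate (x, y, z, in millimetres) from one
neuroimaging experiment; an *experiment* is a single study contrast with its
group sample size; a *dataset* is the set of experiments entering one
meta-analytic contrast.

The text format mirrors the plain-text export used by coordinate databases:

    // Reference=MNI
    // Smith 2020: patients<controls
    // Subjects=23
    42.0  -62.0  46.0
    6.0   -86.0  6.0

    // Jones 2019: patients<controls
    // Subjects=15
    ...

Blank lines separate experiments; any further ``//`` lines inside a block are
treated as comments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator

__all__ = ["TAL", "MNI", "Focus", "Experiment", "Dataset", "SleuthParseError",
           "read_sleuth", "write_sleuth"]

TAL = "TAL"
MNI = "MNI"

_MAX_ABS_MM = 200.0


class SleuthParseError(ValueError):
    """Raised when a foci text file violates the format contract."""


@dataclass(frozen=True)
class Focus:
    """One peak coordinate in millimetres in a named reference space."""

    x: float
    y: float
    z: float
    space: str = MNI

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not (v == v and abs(v) != float("inf")):
                raise ValueError("focus coordinates must be finite")
            if abs(v) > _MAX_ABS_MM:
                raise ValueError(
                    f"|coordinate| exceeds {_MAX_ABS_MM} mm: {(self.x, self.y, self.z)}"
                )
        if self.space not in (TAL, MNI):
            raise ValueError(f"unknown reference space {self.space!r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class Experiment:
    """One study contrast: an id, a sample size and its foci."""

    id: str
    n: int
    foci: tuple[Focus, ...]
    space: str = MNI

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"sample size must be >= 1, got {self.n}")
        if not self.foci:
            raise ValueError(f"experiment {self.id!r} has no foci")
        if self.space not in (TAL, MNI):
            raise ValueError(f"unknown reference space {self.space!r}")
        object.__setattr__(self, "foci", tuple(self.foci))

    @property
    def n_foci(self) -> int:
        return len(self.foci)


@dataclass(frozen=True)
class Dataset:
    """All experiments entering one meta-analytic contrast."""

    contrast_name: str
    experiments: tuple[Experiment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "experiments", tuple(self.experiments))
        ids = [e.id for e in self.experiments]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate experiment ids: {dupes}")

    def __len__(self) -> int:
        return len(self.experiments)

    def __iter__(self) -> Iterator[Experiment]:
        return iter(self.experiments)

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    @property
    def n_foci(self) -> int:
        return sum(e.n_foci for e in self.experiments)

    @property
    def n_subjects(self) -> int:
        return sum(e.n for e in self.experiments)

    @property
    def space(self) -> str:
        spaces = {e.space for e in self.experiments}
        if len(spaces) > 1:
            raise ValueError(f"mixed reference spaces in dataset: {sorted(spaces)}")
        return spaces.pop() if spaces else MNI

    def summary(self) -> str:
        """Counts in the conventional ``(n = ...; ... foci; ... experiments)`` form."""
        return (f"(n = {self.n_subjects}; {self.n_foci} foci; "
                f"{self.n_experiments} experiments)")

    def without(self, experiment_id: str) -> "Dataset":
        """Leave-one-out copy, used by the jackknife."""
        kept = tuple(e for e in self.experiments if e.id != experiment_id)
        if len(kept) == len(self.experiments):
            raise KeyError(f"no experiment with id {experiment_id!r}")
        return replace(self, experiments=kept)


_SUBJECTS_RE = re.compile(r"^//\s*Subjects\s*=\s*(\d+)\s*$", re.IGNORECASE)
_REFERENCE_RE = re.compile(r"^//\s*Reference\s*=\s*(\S+)\s*$", re.IGNORECASE)

_SPACE_ALIASES = {
    "MNI": MNI, "ICBM": MNI, "MNI152": MNI,
    "TAL": TAL, "TALAIRACH": TAL,
}


def read_sleuth(stream: IO[str] | Iterable[str], contrast_name: str = "") -> Dataset:
    """Parse a Sleuth-style foci text stream into a :class:`Dataset`.

    The stream must open with a ``// Reference=<space>`` line, followed by
    per-experiment blocks: one or more ``//`` header lines of which exactly
    one is ``// Subjects=<n>``, then one whitespace-separated ``x y z``
    coordinate per line.  Blocks are separated by blank lines.
    """
    space: str | None = None
    experiments: list[Experiment] = []
    block_labels: list[str] = []
    block_n: int | None = None
    block_foci: list[Focus] = []
    seen_ids: set[str] = set()

    def flush(lineno: int) -> None:
        nonlocal block_labels, block_n, block_foci
        if not block_labels and block_n is None and not block_foci:
            return
        label = "; ".join(block_labels) if block_labels else f"experiment_{len(experiments) + 1}"
        if block_n is None:
            raise SleuthParseError(
                f"block {label!r} (ending near line {lineno}) has no '// Subjects=<n>' annotation"
            )
        if not block_foci:
            raise SleuthParseError(f"block {label!r} has no coordinates")
        uid = label
        k = 2
        while uid in seen_ids:
            uid = f"{label} ({k})"
            k += 1
        seen_ids.add(uid)
        experiments.append(Experiment(id=uid, n=block_n, foci=tuple(block_foci), space=space or MNI))
        block_labels, block_n, block_foci = [], None, []

    lineno = 0
    for lineno, raw in enumerate(iter(stream), start=1):
        line = raw.rstrip("\n").strip()
        if not line:
            flush(lineno)
            continue
        m = _REFERENCE_RE.match(line)
        if m:
            tag = m.group(1).upper()
            if tag not in _SPACE_ALIASES:
                raise SleuthParseError(f"line {lineno}: unknown reference space {m.group(1)!r}")
            space = _SPACE_ALIASES[tag]
            continue
        m = _SUBJECTS_RE.match(line)
        if m:
            block_n = int(m.group(1))
            continue
        if line.startswith("//"):
            text = line[2:].strip()
            if text:
                block_labels.append(text.rstrip(":"))
            continue
        parts = line.split()
        if len(parts) != 3:
            raise SleuthParseError(
                f"line {lineno}: expected 3 coordinates, got {len(parts)}: {line!r}"
            )
        try:
            x, y, z = (float(p) for p in parts)
        except ValueError as exc:
            raise SleuthParseError(f"line {lineno}: non-numeric coordinate in {line!r}") from exc
        if space is None:
            raise SleuthParseError(
                f"line {lineno}: coordinates before a '// Reference=<space>' header"
            )
        block_foci.append(Focus(x, y, z, space=space))
    flush(lineno + 1)

    if not experiments:
        raise SleuthParseError("zero experiments in foci file")
    return Dataset(contrast_name=contrast_name, experiments=tuple(experiments))


def write_sleuth(ds: Dataset, stream: IO[str]) -> None:
    """Write a dataset in the Sleuth-style text format read by :func:`read_sleuth`.

    The output round-trips: parsing it yields an equal dataset.
    """
    stream.write(f"// Reference={ds.space}\n")
    for e in ds.experiments:
        stream.write(f"// {e.id}\n")
        stream.write(f"// Subjects={e.n}\n")
        for f in e.foci:
            stream.write(f"{_fmt(f.x)}\t{_fmt(f.y)}\t{_fmt(f.z)}\n")
        stream.write("\n")


def _fmt(v: float) -> str:
    # repr keeps full double precision so the parse/write round trip is lossless
    return repr(float(v))
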