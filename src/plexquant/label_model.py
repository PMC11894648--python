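"""Isobaric label sets, impurity correction factors, and reporter correction.

Isobaric tags (TMT, TMTpro, iTRAQ) carry isotopic impurities: a fraction of
each channel's true reporter signal is detected in neighboring channels.
Vendors certify these fractions per production batch.  This module models the
channel structure of an n-plex, reads correction-factor templates, assembles
the row-stochastic mixing matrix ``A`` (row i = where channel i's true signal
ends up), and inverts the mixing to recover corrected intensities.

The observed reporter vector relates to the true one by ``y = A.T @ x``.
Correction deletes channels with exactly zero observed intensity (from ``y``
and the corresponding rows/columns of ``A``), solves the reduced square
system by LU factorization, and clamps negative solution entries to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "LabelSet",
    "CorrectionFactors",
    "MixingMatrix",
    "ReporterVector",
    "load_label_set",
    "read_correction_template",
    "build_mixing_matrix",
    "correct_impurities",
    "correct_impurities_matrix",
]


def _tmt_channels(count: int) -> list[str]:
    """Channel names in monoisotopic-mass order: N before C within a nominal mass."""
    names = ["126"]
    mass = 127
    while len(names) < count:
        names.append(f"{mass}N")
        if len(names) < count:
            names.append(f"{mass}C")
        mass += 1
    return names[:count]


#: Preset channel orderings (monoisotopic-mass order, N before C).
PRESETS: dict[str, list[str]] = {
    "TMT10": ["126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131"],
    "TMT11": ["126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131N", "131C"],
    "TMTpro16": _tmt_channels(16),
}


@dataclass(frozen=True)
class LabelSet:
    """The channel structure of one n-plex.

    The channel order is fixed and defines row/column order of every mixing
    matrix and the element order of every reporter-intensity vector.
    """

    name: str
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"duplicate channel names in label set {self.name!r}")
        if not self.channels:
            raise ValueError("label set must have at least one channel")

    @property
    def n(self) -> int:
        return len(self.channels)

    def index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not in label set {self.name!r} "
                f"(channels: {', '.join(self.channels)})"
            ) from None


def load_label_set(name_or_definition: str | Sequence[str]) -> LabelSet:
    """Return a preset label set by name, or build one from an explicit channel list.

    Known presets: ``TMT10``, ``TMT11``, ``TMTpro16``.
    """
    if isinstance(name_or_definition, str):
        if name_or_definition not in PRESETS:
            raise KeyError(
                f"unknown label set preset {name_or_definition!r}; "
                f"known presets: {', '.join(sorted(PRESETS))}"
            )
        return LabelSet(name=name_or_definition, channels=tuple(PRESETS[name_or_definition]))
    channels = tuple(str(c) for c in name_or_definition)
    return LabelSet(name=f"custom{len(channels)}", channels=channels)


@dataclass(frozen=True)
class CorrectionFactors:
    """Off-diagonal impurity fractions: (source, destination, fraction in [0,1)).

    The diagonal is implied as the remainder ``1 - sum(off-diagonal)`` per
    source.  Destinations are named channels, which keeps C-type versus N-type
    leakage (e.g. TMTpro 126 -> 127C and 127N) unambiguous.
    """

    label_set: LabelSet
    entries: tuple[tuple[str, str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        per_source: dict[str, float] = {}
        for src, dst, frac in self.entries:
            self.label_set.index(src)
            self.label_set.index(dst)
            if src == dst:
                raise ValueError(f"correction factor with source == destination ({src!r})")
            if (src, dst) in seen:
                raise ValueError(f"duplicate correction-factor pair ({src!r}, {dst!r})")
            seen.add((src, dst))
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} for ({src!r}, {dst!r}) outside [0, 1]")
            per_source[src] = per_source.get(src, 0.0) + frac
        for src, total in per_source.items():
            if total >= 1.0:
                raise ValueError(
                    f"off-diagonal fractions for source {src!r} sum to {total} >= 1"
                )


def read_correction_template(path: str | Path, label_set: LabelSet) -> CorrectionFactors:
    """Read a tab-separated impurity template: ``source  destination  percent``.

    Percentages (as on vendor certificates of analysis) are converted to
    fractions.  Lines starting with ``#`` are ignored.  An empty template
    yields identity correction.
    """
    path = Path(path)
    entries: list[tuple[str, str, float]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if parts[0].lower() == "source":
                continue  # header
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            src, dst, pct_s = parts
            try:
                pct = float(pct_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: unparseable percentage {pct_s!r}") from None
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"{path}:{lineno}: percentage {pct} outside [0, 100]")
            for name in (src, dst):
                if name not in label_set.channels:
                    raise ValueError(
                        f"{path}:{lineno}: unknown channel {name!r} for label set "
                        f"{label_set.name!r}"
                    )
            entries.append((src, dst, pct / 100.0))
    return CorrectionFactors(label_set=label_set, entries=tuple(entries))


def write_correction_template(cf: CorrectionFactors, path: str | Path) -> None:
    """Write correction factors back to the template TSV dialect (percent units)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("source\tdestination\tpercent\n")
        for src, dst, frac in cf.entries:
            fh.write(f"{src}\t{dst}\t{frac * 100!r}\n")


@dataclass(frozen=True)
class MixingMatrix:
    """Row-stochastic n x n impurity matrix.

    ``A[i, j]`` is the fraction of channel i's true signal observed in
    channel j; rows sum to 1.
    """

    A: np.ndarray
    label_set: LabelSet

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        n = self.label_set.n
        if A.shape != (n, n):
            raise ValueError(f"mixing matrix shape {A.shape} != ({n}, {n})")
        if np.any(A < 0):
            raise ValueError("mixing matrix has negative entries")
        if not np.allclose(A.sum(axis=1), 1.0, atol=1e-12, rtol=0.0):
            raise ValueError("mixing matrix rows must sum to 1 within 1e-12")
        object.__setattr__(self, "A", A)

    @property
    def is_identity(self) -> bool:
        return bool(np.array_equal(self.A, np.eye(self.label_set.n)))


def build_mixing_matrix(label_set: LabelSet, cf: CorrectionFactors) -> MixingMatrix:
    """Assemble the mixing matrix from off-diagonal correction factors.

    The diagonal is the remainder ``1 - sum(row off-diagonal)``; a
    non-positive diagonal means the leakage is over-specified and is a hard
    error.
    """
    n = label_set.n
    A = np.zeros((n, n))
    for src, dst, frac in cf.entries:
        A[label_set.index(src), label_set.index(dst)] = frac
    diag = 1.0 - A.sum(axis=1)
    bad = np.nonzero(diag <= 0)[0]
    if bad.size:
        names = ", ".join(label_set.channels[i] for i in bad)
        raise ValueError(f"over-specified leakage: non-positive diagonal for channel(s) {names}")
    A[np.arange(n), np.arange(n)] = diag
    return MixingMatrix(A=A, label_set=label_set)


@dataclass
class ReporterVector:
    """Observed reporter intensities ``y`` and, once corrected, ``x``."""

    y: np.ndarray
    x: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if np.any(self.y < 0):
            raise ValueError("observed reporter intensities must be non-negative")
        if self.x is not None:
            self.x = np.asarray(self.x, dtype=float)
            if self.x.shape != self.y.shape:
                raise ValueError("corrected vector length differs from observed")


def _correct_single(y: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Solve ``A.T x = y`` on the nonzero-channel submatrix; clamp negatives."""
    nz = np.nonzero(y != 0.0)[0]
    x = np.zeros_like(y)
    if nz.size == 0:
        return x
    sub = A[np.ix_(nz, nz)].T
    try:
        lu, piv = scipy.linalg.lu_factor(sub)
        sol = scipy.linalg.lu_solve((lu, piv), y[nz])
    except (scipy.linalg.LinAlgError, ValueError):
        logger.warning(
            "singular reduced mixing matrix (%d channels); passing raw intensities through",
            nz.size,
        )
        x[nz] = y[nz]
        return x
    if not np.all(np.isfinite(sol)):
        logger.warning(
            "singular reduced mixing matrix (non-finite solution); passing raw intensities through"
        )
        x[nz] = y[nz]
        return x
    np.clip(sol, 0.0, None, out=sol)
    x[nz] = sol
    return x


def correct_impurities(y: ReporterVector | np.ndarray | Sequence[float], M: MixingMatrix) -> ReporterVector:
    """Impurity-correct one observed reporter vector.

    Channels with exactly zero observed intensity are removed from the system
    (and reported as zero in the result); the reduced system ``A.T x = y`` is
    solved by LU decomposition and negative solution elements are set to
    zero.  A singular reduced system passes the raw values through with a
    logged warning rather than dropping the spectrum.
    """
    vec = y if isinstance(y, ReporterVector) else ReporterVector(y=np.asarray(y, dtype=float))
    if vec.y.shape != (M.label_set.n,):
        raise ValueError(f"reporter vector length {vec.y.shape} != plex size {M.label_set.n}")
    vec.x = _correct_single(vec.y, M.A)
    return vec


def correct_impurities_matrix(Y: np.ndarray, M: MixingMatrix) -> np.ndarray:
    """Impurity-correct a stack of reporter vectors (rows = spectra).

    Rows sharing a zero pattern share one LU factorization.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != M.label_set.n:
        raise ValueError(f"expected (n_psms, {M.label_set.n}) array, got {Y.shape}")
    X = np.zeros_like(Y)
    masks = Y != 0.0
    # group rows by zero pattern so each pattern is factorized once
    pattern_codes = masks @ (1 << np.arange(Y.shape[1], dtype=object))
    for code in np.unique(pattern_codes):
        rows = np.nonzero(pattern_codes == code)[0]
        nz = np.nonzero(masks[rows[0]])[0]
        if nz.size == 0:
            continue
        sub = M.A[np.ix_(nz, nz)].T
        try:
            lu, piv = scipy.linalg.lu_factor(sub)
            sol = scipy.linalg.lu_solve((lu, piv), Y[np.ix_(rows, nz)].T).T
        except (scipy.linalg.LinAlgError, ValueError):
            logger.warning(
                "singular reduced mixing matrix for %d spectra; passing raw intensities through",
                rows.size,
            )
            X[np.ix_(rows, nz)] = Y[np.ix_(rows, nz)]
            continue
        if not np.all(np.isfinite(sol)):
            logger.warning(
                "singular reduced mixing matrix for %d spectra (non-finite solution); "
                "passing raw intensities through",
                rows.size,
            )
            X[np.ix_(rows, nz)] = Y[np.ix_(rows, nz)]
            continue
        np.clip(sol, 0.0, None, out=sol)
        X[np.ix_(rows, nz)] = sol
    return X
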