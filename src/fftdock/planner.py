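"""Accelerator memory model, work accounting, and the stage profiler.

Many-core accelerators that parallelize the docking search over rotation
angles (one rotation per thread, native execution on the device) need the
FFT input and output arrays *per thread*: two N³ arrays of single-precision
complex values, i.e. 16·N³ bytes per thread.  With a fixed on-board memory
budget that caps either the FFT size N or the number of threads that can
run — e.g. an 8 GB budget with 240 threads caps N at 127 (real-valued bound
127.7), while 60 threads allow N up to 202 (bound 202.7).  The model here is
the formula-only bound; real per-thread footprints are somewhat larger, so
usable thread counts are upper bounds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:
    from .fft_search import DockingResult

__all__ = [
    "COMPLEX_FLOAT_BYTES",
    "MemoryPlan",
    "StageProfile",
    "fft_thread_bytes",
    "max_fft_size",
    "usable_threads",
    "pose_count",
    "make_plan",
    "profile_run",
]

#: Bytes of one single-precision complex value (two float32).
COMPLEX_FLOAT_BYTES: int = 8

#: Arrays held per thread by the in-place-less 3D FFT: input + output.
ARRAYS_PER_THREAD: int = 2


@dataclass(frozen=True)
class MemoryPlan:
    """Memory plan for angle-parallel execution under a fixed budget."""

    budget_bytes: float
    n_threads: int
    fft_size: int  # N
    per_thread_bytes: int  # 16·N³
    max_n_real: float  # real-valued bound on N for this budget/thread count
    max_n: int  # largest integer N fitting the budget
    usable_threads: int  # threads that fit at fft_size under the budget

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_tsv(self) -> str:
        d = asdict(self)
        return "\n".join(f"{k}\t{v}" for k, v in d.items()) + "\n"


def fft_thread_bytes(n: int) -> int:
    """Per-thread FFT memory: input + output array of N³ complex floats = 16·N³ bytes."""
    n = int(n)
    if n < 1:
        raise ValueError(f"N must be >= 1, got {n}")
    return ARRAYS_PER_THREAD * COMPLEX_FLOAT_BYTES * n**3


def max_fft_size(budget: float, threads: int) -> tuple[float, int]:
    """Largest FFT size N fitting ``threads`` angle-parallel workers in ``budget`` bytes.

    Returns ``(N_real, N_max)``: the real-valued bound
    ``(budget / threads / 16)^(1/3)`` and the largest integer N with
    ``threads · 16 · N³ ≤ budget``.
    """
    if not budget > 0:
        raise ValueError(f"budget must be > 0, got {budget}")
    if threads < 1:
        raise ValueError(f"threads must be >= 1, got {threads}")
    per_n3 = ARRAYS_PER_THREAD * COMPLEX_FLOAT_BYTES
    n_real = (budget / threads / per_n3) ** (1.0 / 3.0)
    n_max = max(0, int(n_real) + 2)
    while n_max > 0 and threads * per_n3 * n_max**3 > budget:
        n_max -= 1
    return n_real, n_max


def usable_threads(budget: float, n: int, hw_threads: int) -> int:
    """Threads that fit at FFT size N under the budget (formula-only model).

    ``min(hw_threads, floor(budget / 16·N³))``.  Real per-thread footprints
    exceed 16·N³, so this is an upper bound.  Returns 0 with a warning if
    not even one thread fits.
    """
    if not budget > 0 or n < 1 or hw_threads < 1:
        raise ValueError("budget, N and hw_threads must all be positive")
    fit = int(budget // fft_thread_bytes(n))
    if fit < 1:
        warnings.warn(
            f"budget {budget:g} B cannot hold even one thread at N={n} "
            f"({fft_thread_bytes(n)} B/thread)",
            stacklevel=2,
        )
        return 0
    return min(hw_threads, fit)


def pose_count(n_theta: int, n: int) -> int:
    """Total candidate poses of an exhaustive run: n_θ × N³ (exact integer)."""
    if n_theta < 0 or n < 1:
        raise ValueError("n_theta must be >= 0 and N >= 1")
    return int(n_theta) * int(n) ** 3


def make_plan(budget: float, threads: int, fft_size: int | None = None) -> MemoryPlan:
    """Assemble a full :class:`MemoryPlan` for a budget / thread count.

    If ``fft_size`` is omitted the plan is built at the largest N that fits.
    """
    n_real, n_max = max_fft_size(budget, threads)
    n = int(fft_size) if fft_size is not None else max(n_max, 1)
    return MemoryPlan(
        budget_bytes=float(budget),
        n_threads=int(threads),
        fft_size=n,
        per_thread_bytes=fft_thread_bytes(n),
        max_n_real=n_real,
        max_n=n_max,
        usable_threads=usable_threads(budget, n, threads),
    )


@dataclass(frozen=True)
class StageProfile:
    """Per-stage timing table of one docking run (P1–P9 + total)."""

    rows: tuple[tuple[str, float, float], ...]  # (stage, seconds, percent)
    total_seconds: float

    def to_tsv(self) -> str:
        lines = ["stage\tseconds\tpercent"]
        for stage, sec, pct in self.rows:
            lines.append(f"{stage}\t{sec:.6f}\t{pct:.3f}")
        lines.append(f"Total\t{self.total_seconds:.6f}\t100.000")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "stages": [
                    {"stage": s, "seconds": sec, "percent": pct} for s, sec, pct in self.rows
                ],
                "total_seconds": self.total_seconds,
            },
            indent=2,
        )


def profile_run(result: "DockingResult") -> StageProfile:
    """Turn a profiled docking run into the canonical 9-stage time table.

    Emits one row per stage P1–P9 with seconds and percentage of total
    (percentages sum to 100 up to floating-point rounding), plus the total.
    Raises if the run was executed with profiling disabled.
    """
    from .fft_search import STAGES

    if result.timings is None:
        raise ValueError("docking run was executed with profiling disabled")
    seconds = [float(result.timings.get(stage, 0.0)) for stage in STAGES]
    total = sum(seconds)
    if total > 0:
        percents = [100.0 * s / total for s in seconds]
    else:
        percents = [0.0 for _ in seconds]
    rows = tuple(zip(STAGES, seconds, percents))
    return StageProfile(rows=rows, total_seconds=total)
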