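"""Summary statistics over one or many runs.

Mirrors the analysis surface of the simulator: per-run population step
functions, averages over replicate runs, and histograms of clone sizes, rule
executions and internal-state values.  A clone is all individuals descended
from a single founder (root); its size at time ``t`` is the number of its
living individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import RunResult
from .lineage import MERGED_SPECIES, LineageForest

__all__ = [
    "Histogram",
    "population_timeseries",
    "average_population",
    "time_integrated_population",
    "clone_size_histogram",
    "rule_execution_histogram",
    "internal_state_histogram",
    "state_increments",
]


@dataclass
class Histogram:
    """Labelled counts, optionally normalized to percentages."""

    labels: list
    counts: np.ndarray
    normalized: bool = False

    @property
    def percentages(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return 100.0 * self.counts / total

    @property
    def values(self) -> np.ndarray:
        return self.percentages if self.normalized else self.counts

    def to_tsv(self) -> str:
        head = "label\tpercentage" if self.normalized else "label\tcount"
        rows = [head]
        for label, v in zip(self.labels, self.values):
            rows.append(
                f"{label}\t{float(v)!r}" if self.normalized
                else f"{label}\t{int(v)}"
            )
        return "\n".join(rows) + "\n"


def population_timeseries(run: RunResult, species: str):
    """Right-continuous step function (times, sizes) of one species."""
    return run.series(species)


def _zoh(times: np.ndarray, sizes: np.ndarray, grid: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(times, grid, side="right") - 1
    idx = np.clip(idx, 0, len(sizes) - 1)
    return sizes[idx].astype(float)


def average_population(
    runs: list[RunResult], species: str, grid=None
):
    """Pointwise mean (and standard error) of the population step functions.

    Returns ``(grid, mean, sem)``.  The default grid is 200 uniform points
    over ``[0, T]`` of the first run.
    """
    if not runs:
        raise ValueError("need at least one run")
    if grid is None:
        grid = np.linspace(0.0, runs[0].end_time, 200)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    samples = np.empty((len(runs), grid.size))
    for i, r in enumerate(runs):
        times, sizes = r.series(species)
        samples[i] = _zoh(times, sizes, grid)
    mean = samples.mean(axis=0)
    if len(runs) > 1:
        sem = samples.std(axis=0, ddof=1) / np.sqrt(len(runs))
    else:
        sem = np.zeros_like(mean)
    return grid, mean, sem


def time_integrated_population(run: RunResult, species: str) -> float:
    """Integral of the population step function over the recorded span
    (person-time; denominator of per-capita rate estimates)."""
    times, sizes = run.series(species)
    edges = np.append(times, run.end_time)
    return float(np.sum(sizes * np.diff(edges)))


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

def _matches(species: str, flt) -> bool:
    if flt is None:
        return True
    if isinstance(flt, str):
        return species == flt
    return species in flt


def _clone_size(forest: LineageForest, root: int, t: float, member) -> int:
    size = 0
    stack = [root]
    nodes = forest.nodes
    while stack:
        n = nodes[stack.pop()]
        if (
            n.species != MERGED_SPECIES
            and _matches(n.species, member)
            and n.is_alive_at(t)
        ):
            size += 1
        stack.extend(n.children)
    return size


def clone_size_histogram(
    runs: list[RunResult],
    founder_species=None,
    member_species=None,
    t: float | None = None,
    include_extinct: bool = True,
) -> Histogram:
    """Percentage histogram of clone sizes pooled across runs.

    For every root whose species matches ``founder_species``, the clone size
    is the number of living descendants (founder included) at ``t`` matching
    ``member_species``.  Extinct clones contribute a size-0 bin unless
    ``include_extinct`` is false.  ``t`` defaults to each run's end time.
    """
    sizes: list[int] = []
    for r in runs:
        at = r.end_time if t is None else t
        if not 0.0 <= at <= r.end_time:
            raise ValueError(f"t = {at} outside [0, {r.end_time}]")
        for root in r.forest.roots:
            node = r.forest.nodes[root]
            if node.species == MERGED_SPECIES or not _matches(
                node.species, founder_species
            ):
                continue
            size = _clone_size(r.forest, root, at, member_species)
            if size == 0 and not include_extinct:
                continue
            sizes.append(size)
    labels = sorted(set(sizes))
    counts = np.array([sizes.count(s) for s in labels], dtype=np.int64)
    return Histogram(labels=labels, counts=counts, normalized=True)


def rule_execution_histogram(runs: list[RunResult]) -> Histogram:
    """Total firings per rule, pooled across runs."""
    if not runs:
        raise ValueError("need at least one run")
    names = runs[0].rule_names
    totals = {name: 0 for name in names}
    for r in runs:
        for name, n in r.rule_counts().items():
            totals[name] += n
    return Histogram(
        labels=list(names),
        counts=np.array([totals[n] for n in names], dtype=np.int64),
    )


def internal_state_histogram(
    runs: list[RunResult],
    state_name: str,
    t="all-events",
    bins=None,
) -> Histogram:
    """Histogram of one internal state's values pooled across runs.

    At a time point ``t`` only living individuals contribute; with the
    default ``"all-events"`` every node ever created contributes.  Dup
    instances are pooled.
    """
    values: list[float] = []
    found = False
    for r in runs:
        for node in r.forest.nodes.values():
            if not node.states or state_name not in node.states:
                continue
            found = True
            if t != "all-events" and not node.is_alive_at(float(t)):
                continue
            values.extend(node.states[state_name])
    if not found:
        raise ValueError(f"internal state {state_name!r} not recorded in any run")
    arr = np.asarray(values, dtype=float)
    if bins is None:
        uniq = np.unique(arr)
        if uniq.size <= 64:
            counts = np.array(
                [(arr == u).sum() for u in uniq], dtype=np.int64
            )
            return Histogram(labels=[float(u) for u in uniq], counts=counts)
        bins = 20
    counts, edges = np.histogram(arr, bins=bins)
    labels = [f"[{lo:.6g},{hi:.6g})" for lo, hi in zip(edges[:-1], edges[1:])]
    return Histogram(labels=labels, counts=counts.astype(np.int64))


def state_increments(runs: list[RunResult], state_name: str) -> np.ndarray:
    """Per-inheritance increments of one internal state across runs.

    Collects ``child - parent`` over division edges where both parent and
    child carry the state (the updater was applied); transform carry-overs
    and initial-value resets are excluded.  Dup instances are pooled.
    """
    out: list[float] = []
    for r in runs:
        nodes = r.forest.nodes
        for node in nodes.values():
            if node.end_cause != "division":
                continue
            if not node.states or state_name not in node.states:
                continue
            pvals = node.states[state_name]
            for child_id in node.children:
                child = nodes[child_id]
                if not child.states or state_name not in child.states:
                    continue
                for pv, cv in zip(pvals, child.states[state_name]):
                    out.append(cv - pv)
    return np.asarray(out, dtype=float)
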