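"""On-disk run archives: the entire data history, human-diffable.

An archive directory holds the program snapshot, a manifest and one
subdirectory per seed with the event log, the node table (the full lineage
forest with internal-state values), the population step function and the
Newick trees.  Reloading an archive reproduces every statistic bit-identically
without re-simulation: floats are serialized with ``repr`` (shortest exact
decimal) so they round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .engine import EventRecord, RunResult
from .lineage import LineageForest, merge_forest, to_newick
from .program_model import Program, parse_program, validate_program

__all__ = ["RunArchive", "save_archive", "load_archive"]

_EVENTS_HEADER = "time\trule_index\toutcome_index\tparent\tchildren\ttransforms"
_NODES_HEADER = "node_id\tspecies\tparent\tbirth_time\tend_time\tend_cause\tstates"


class RunArchive:
    """A loaded archive: program, manifest and reconstructed runs."""

    def __init__(self, path: Path, program: Program, runs: list[RunResult],
                 manifest: dict):
        self.path = path
        self.program = program
        self.runs = runs
        self.manifest = manifest


def _write_events(path: Path, run: RunResult) -> None:
    lines = [_EVENTS_HEADER]
    for ev in run.events:
        transforms = ";".join(
            f"{node}:{src}>{tgt if tgt is not None else '{0}'}"
            for node, src, tgt in ev.conditional_transforms
        )
        children = ",".join(str(c) for c in ev.child_nodes)
        lines.append(
            f"{ev.time!r}\t{ev.channel[0]}\t{ev.channel[1]}\t"
            f"{ev.parent_node}\t{children}\t{transforms}"
        )
    path.write_text("\n".join(lines) + "\n")


def _read_events(path: Path) -> list[EventRecord]:
    events = []
    with path.open() as fh:
        header = fh.readline()
        assert header.strip() == _EVENTS_HEADER.strip()
        for line in fh:
            time_s, rule_s, out_s, parent_s, children_s, transforms_s = (
                line.rstrip("\n").split("\t")
            )
            children = tuple(
                int(c) for c in children_s.split(",") if c
            )
            transforms = []
            if transforms_s:
                for item in transforms_s.split(";"):
                    node_s, rest = item.split(":", 1)
                    src, tgt = rest.split(">", 1)
                    transforms.append(
                        (int(node_s), src, None if tgt == "{0}" else tgt)
                    )
            events.append(
                EventRecord(
                    time=float(time_s),
                    channel=(int(rule_s), int(out_s)),
                    parent_node=int(parent_s),
                    child_nodes=children,
                    conditional_transforms=transforms,
                )
            )
    return events


def _write_nodes(path: Path, run: RunResult) -> None:
    lines = [_NODES_HEADER]
    for node_id in sorted(run.forest.nodes):
        n = run.forest.nodes[node_id]
        states = (
            json.dumps({k: list(v) for k, v in n.states.items()})
            if n.states
            else ""
        )
        lines.append(
            f"{n.node_id}\t{n.species}\t"
            f"{n.parent if n.parent is not None else ''}\t"
            f"{n.birth_time!r}\t{n.end_time!r}\t{n.end_cause}\t{states}"
        )
    path.write_text("\n".join(lines) + "\n")


def _read_nodes(path: Path, end_time: float) -> LineageForest:
    forest = LineageForest()
    forest.end_time = end_time
    max_id = 0
    with path.open() as fh:
        header = fh.readline()
        assert header.strip() == _NODES_HEADER.strip()
        for line in fh:
            nid_s, species, parent_s, birth_s, end_s, cause, states_s = (
                line.rstrip("\n").split("\t")
            )
            from .lineage import LineageNode

            node = LineageNode(
                node_id=int(nid_s),
                species=species,
                parent=int(parent_s) if parent_s else None,
                birth_time=float(birth_s),
                end_time=float(end_s),
                end_cause=cause,
                states=(
                    {k: tuple(v) for k, v in json.loads(states_s).items()}
                    if states_s
                    else None
                ),
            )
            forest.nodes[node.node_id] = node
            max_id = max(max_id, node.node_id)
    for node in forest.nodes.values():
        if node.parent is None:
            forest.roots.append(node.node_id)
        else:
            forest.nodes[node.parent].children.append(node.node_id)
    forest.roots.sort()
    for node in forest.nodes.values():
        node.children.sort()
    forest._next_id = max_id + 1
    return forest


def _write_populations(path: Path, run: RunResult) -> None:
    species = list(run.population_series)
    lines = ["time\t" + "\t".join(species)]
    for i, t in enumerate(run.times):
        row = "\t".join(str(int(run.population_series[sp][i])) for sp in species)
        lines.append(f"{float(t)!r}\t{row}")
    path.write_text("\n".join(lines) + "\n")


def _read_populations(path: Path):
    with path.open() as fh:
        species = fh.readline().rstrip("\n").split("\t")[1:]
        times = []
        series: dict[str, list[int]] = {sp: [] for sp in species}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            times.append(float(parts[0]))
            for sp, v in zip(species, parts[1:]):
                series[sp].append(int(v))
    return (
        np.asarray(times),
        {sp: np.asarray(v, dtype=np.int64) for sp, v in series.items()},
    )


def save_archive(
    out_dir,
    program_text: str,
    runs: list[RunResult],
    t_span: float,
    *,
    merge: bool = False,
    living_only: bool = False,
    legacy_first_update: bool = False,
    state_names: list[str] | None = None,
) -> Path:
    """Write a structured archive directory for a batch of runs."""
    from .lineage import internal_state_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "program.xml").write_text(program_text)

    program = validate_program(parse_program(program_text))
    if state_names is None:
        state_names = sorted(
            {ist.name for defs in program.internal_states.values() for ist in defs}
        )

    manifest: dict = {
        "tool": "estg",
        "version": __version__,
        "t_span": repr(float(t_span)),
        "merge": merge,
        "living_only": living_only,
        "legacy_first_update": legacy_first_update,
        "seeds": [r.seed for r in runs],
        "runs": [],
    }
    for run in runs:
        run_dir = out / "runs" / str(run.seed)
        run_dir.mkdir(parents=True, exist_ok=True)
        _write_events(run_dir / "events.tsv", run)
        _write_nodes(run_dir / "nodes.tsv", run)
        _write_populations(run_dir / "populations.tsv", run)
        _write_trees(run_dir / "trees.nwk", run, merge=merge,
                     living_only=living_only)
        for name in state_names:
            table = internal_state_table(run.forest, name, program)
            (run_dir / f"state_{name}.tsv").write_text(table)
        manifest["runs"].append(
            {
                "seed": run.seed,
                "end_time": repr(run.end_time),
                "end_reason": run.end_reason,
                "n_events": len(run.events),
                "rule_names": list(run.rule_names),
                "channel_counts": {
                    f"{r}:{o}": n for (r, o), n in sorted(run.channel_counts.items())
                },
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return out


def _write_trees(path: Path, run: RunResult, *, merge: bool,
                 living_only: bool) -> None:
    lines = []
    if merge and len(run.forest.roots) >= 2:
        merged = merge_forest(run.forest, run.forest.roots)
        try:
            lines.append(to_newick(merged, 0, living_only=living_only))
        except ValueError:
            pass  # fully extinct forest with living_only: nothing to export
    else:
        for root in run.forest.roots:
            try:
                lines.append(to_newick(run.forest, root, living_only=living_only))
            except ValueError:
                continue
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def load_archive(path) -> RunArchive:
    """Reload an archive; statistics recomputed from it match the originals
    bit-identically."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    program_text = (path / "program.xml").read_text()
    program = validate_program(parse_program(program_text))
    runs = []
    for entry in manifest["runs"]:
        run_dir = path / "runs" / str(entry["seed"])
        end_time = float(entry["end_time"])
        times, series = _read_populations(run_dir / "populations.tsv")
        runs.append(
            RunResult(
                seed=entry["seed"],
                events=_read_events(run_dir / "events.tsv"),
                channel_counts={
                    tuple(int(x) for x in k.split(":")): v
                    for k, v in entry["channel_counts"].items()
                },
                times=times,
                population_series=series,
                forest=_read_nodes(run_dir / "nodes.tsv", end_time),
                end_time=end_time,
                end_reason=entry["end_reason"],
                rule_names=tuple(entry["rule_names"]),
            )
        )
    return RunArchive(path, program, runs, manifest)
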