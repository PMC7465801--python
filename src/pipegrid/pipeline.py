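"""Declarative pipeline definition and prefix-sharing combinatorial runner.

A pipeline is an ordered list of steps, each owning a disjoint set of
parameter names. Given a mapping from parameter to alternative values, the
engine enumerates every combination (or a subset) and executes them over a
prefix tree: any two combinations that agree on all parameters of steps
``<= j`` share a single execution of step ``j``. Traversal is depth-first,
so at most one intermediate state is live per pipeline depth and no
intermediate is ever written to disk. Per-step evaluators run at every tree
node and their payloads, together with wall-clock timings and statuses, are
compiled into tidy per-step tables.

An optional append-only JSON-lines log makes runs resumable: nodes already
recorded are not re-evaluated, and fully recorded subtrees are skipped
outright.
"""

from __future__ import annotations

import inspect
import json
import os
import time
import zlib
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StepSpec",
    "PipelineDefinition",
    "enumerate_combinations",
    "build_prefix_tree",
    "PrefixNode",
    "RunRecord",
    "RunResults",
    "run_pipeline",
    "aggregate_results",
]


# ---------------------------------------------------------------------------
# definition


@dataclass(frozen=True)
class StepSpec:
    """One pipeline step.

    ``operation(state, **params)`` returns the next state; if its signature
    accepts a ``seed`` keyword that is not a declared parameter, the engine
    injects a deterministic per-node seed. ``evaluator(state)`` (optional)
    returns a JSON-serializable payload; ``aggregator`` (optional) turns the
    step's long table of payloads into a custom tidy table.
    """

    name: str
    operation: Callable[..., Any]
    param_names: tuple = ()
    evaluator: Callable[[Any], Any] | None = None
    aggregator: Callable[[pd.DataFrame], pd.DataFrame] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "param_names", tuple(self.param_names))


class PipelineDefinition:
    """Validated ordered list of :class:`StepSpec`.

    ``initiator(raw)`` (optional) prepares a raw dataset into the input
    state of the first step.
    """

    def __init__(
        self,
        steps: Sequence[StepSpec],
        initiator: Callable[[Any], Any] | None = None,
    ) -> None:
        steps = list(steps)
        if not steps:
            raise ValueError("a pipeline needs at least one step")
        names = [s.name for s in steps]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate step names in {names}")
        seen: dict[str, str] = {}
        for s in steps:
            for p in s.param_names:
                if p in seen:
                    raise ValueError(
                        f"parameter {p!r} owned by both {seen[p]!r} and {s.name!r}"
                    )
                seen[p] = s.name
        self.steps = steps
        self.initiator = initiator

    @property
    def param_names(self) -> list:
        return [p for s in self.steps for p in s.param_names]

    def step_of_param(self, param: str) -> str:
        for s in self.steps:
            if param in s.param_names:
                return s.name
        raise KeyError(param)

    def __len__(self) -> int:
        return len(self.steps)

    def __repr__(self) -> str:
        parts = [f"{s.name}({', '.join(s.param_names)})" for s in self.steps]
        return "PipelineDefinition[" + " -> ".join(parts) + "]"


def define_pipeline(
    steps: Sequence[StepSpec], initiator: Callable[[Any], Any] | None = None
) -> PipelineDefinition:
    return PipelineDefinition(steps, initiator)


# ---------------------------------------------------------------------------
# combination enumeration


def enumerate_combinations(
    pipeline: PipelineDefinition,
    alternatives: Mapping[str, Sequence],
    subset: Callable[[dict], bool] | Mapping[str, Sequence] | None = None,
) -> list:
    """All full parameter assignments, in deterministic order.

    Order is lexicographic by step order, then by parameter order within a
    step, then by alternative declaration order. ``subset`` is either a
    predicate over assignment dicts or a mapping from parameter to the
    allowed values.
    """
    params = pipeline.param_names
    unknown = set(alternatives) - set(params)
    if unknown:
        raise ValueError(f"alternatives for unknown parameters: {sorted(unknown)}")
    missing = [p for p in params if p not in alternatives or not list(alternatives[p])]
    if missing:
        raise ValueError(f"no alternatives given for parameters: {missing}")

    if isinstance(subset, Mapping):
        allowed = {k: list(v) for k, v in subset.items()}

        def keep(a: dict) -> bool:
            return all(a[k] in v for k, v in allowed.items())

    elif subset is None:
        def keep(a: dict) -> bool:
            return True
    else:
        keep = subset

    combos: list = []

    def rec(i: int, acc: dict) -> None:
        if i == len(params):
            if keep(acc):
                combos.append(dict(acc))
            return
        for v in alternatives[params[i]]:
            acc[params[i]] = v
            rec(i + 1, acc)
            del acc[params[i]]

    rec(0, {})
    if not combos:
        raise ValueError("subset filter removed every combination")
    return combos


# ---------------------------------------------------------------------------
# prefix tree


@dataclass
class PrefixNode:
    """A distinct partial assignment covering all parameters of steps <= step_index."""

    step_index: int
    assignment: dict
    children: list = field(default_factory=list)
    leaf_indices: list = field(default_factory=list)

    def key(self) -> str:
        items = sorted(self.assignment.items())
        return f"s{self.step_index}|" + "|".join(f"{k}={v!r}" for k, v in items)


def build_prefix_tree(
    plan: Sequence[dict], pipeline: PipelineDefinition
) -> list:
    """Group a combination plan into a forest of prefix nodes (roots = step 0).

    Leaves at the deepest level correspond 1:1 to plan entries; each
    distinct prefix occurs exactly once. Child order follows first
    occurrence in the plan, i.e. alternative declaration order.
    """
    if not plan:
        raise ValueError("empty combination plan")

    def build_level(step_idx: int, indices: list, prefix: dict) -> list:
        step = pipeline.steps[step_idx]
        groups: dict = {}
        order: list = []
        for i in indices:
            sub = tuple((p, plan[i][p]) for p in step.param_names)
            if sub not in groups:
                groups[sub] = []
                order.append(sub)
            groups[sub].append(i)
        nodes = []
        for sub in order:
            assignment = dict(prefix)
            assignment.update(dict(sub))
            node = PrefixNode(step_idx, assignment, leaf_indices=groups[sub])
            if step_idx + 1 < len(pipeline.steps):
                node.children = build_level(step_idx + 1, groups[sub], assignment)
            nodes.append(node)
        return nodes

    return build_level(0, list(range(len(plan))), {})


def tree_level_sizes(roots: list, n_steps: int) -> list:
    sizes = [0] * n_steps
    stack = list(roots)
    while stack:
        node = stack.pop()
        sizes[node.step_index] += 1
        stack.extend(node.children)
    return sizes


# ---------------------------------------------------------------------------
# execution


@dataclass
class RunRecord:
    """Outcome of one prefix-tree node for one dataset."""

    dataset: str
    step: str
    step_index: int
    assignment: dict
    status: str  # "ok" | "error" | "skipped"
    elapsed: float = 0.0
    payload: Any = None
    message: str = ""
    node_key: str = ""
    leaf_indices: list = field(default_factory=list)

    def to_json(self) -> str:
        def default(o: Any):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.bool_,)):
                return bool(o)
            raise TypeError(f"payload not JSON-serializable: {type(o)}")

        return json.dumps(
            {
                "dataset": self.dataset,
                "step": self.step,
                "step_index": self.step_index,
                "assignment": self.assignment,
                "status": self.status,
                "elapsed": self.elapsed,
                "payload": self.payload,
                "message": self.message,
                "node_key": self.node_key,
                "leaf_indices": self.leaf_indices,
            },
            default=default,
        )


def node_seed(global_seed: int, dataset_id: str, node_key: str) -> int:
    """Stable per-node seed below 2**31, independent of sibling order."""
    h = zlib.crc32(f"{global_seed}|{dataset_id}|{node_key}".encode())
    return int(h & 0x7FFFFFFF)


def _accepts_seed(op: Callable, param_names: tuple) -> bool:
    try:
        sig = inspect.signature(op)
    except (TypeError, ValueError):
        return False
    if "seed" in param_names:
        return False
    for p in sig.parameters.values():
        if p.kind == inspect.Parameter.VAR_KEYWORD:
            return True
        if p.name == "seed":
            return True
    return False


class RunResults:
    """Collection of :class:`RunRecord` plus the pipeline that produced them."""

    def __init__(self, pipeline: PipelineDefinition, records: list | None = None):
        self.pipeline = pipeline
        self.records: list = list(records or [])

    def merge(self, other: "RunResults") -> "RunResults":
        if [s.name for s in other.pipeline.steps] != [
            s.name for s in self.pipeline.steps
        ]:
            raise ValueError("cannot merge results from different pipelines")
        merged = RunResults(self.pipeline, self.records + other.records)
        return merged

    def aggregate(self) -> dict:
        return aggregate_results(self.records, self.pipeline)

    def timings(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"dataset": r.dataset, "step": r.step, "status": r.status,
                   "elapsed": r.elapsed}
            row.update(r.assignment)
            rows.append(row)
        return pd.DataFrame(rows)

    def errors(self) -> pd.DataFrame:
        rows = [
            {"dataset": r.dataset, "step": r.step, "message": r.message,
             **r.assignment}
            for r in self.records
            if r.status == "error"
        ]
        return pd.DataFrame(rows, columns=["dataset", "step", "message"] if not rows else None)

    def to_csv(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for step, table in self.aggregate().items():
            table.to_csv(os.path.join(out_dir, f"{step}.csv"), index=False)
        self.timings().to_csv(os.path.join(out_dir, "timings.csv"), index=False)
        self.errors().to_csv(os.path.join(out_dir, "errors.csv"), index=False)


def _flatten_payload(payload: Any) -> dict:
    if payload is None:
        return {}
    if isinstance(payload, Mapping):
        out = {}
        for k, v in payload.items():
            if isinstance(v, Mapping):
                for k2, v2 in v.items():
                    out[f"{k}_{k2}"] = v2
            else:
                out[k] = v
        return out
    return {"value": payload}


def aggregate_results(
    records: Iterable[RunRecord], pipeline: PipelineDefinition
) -> dict:
    """One long-format table per step: a row per (dataset, leaf combination).

    Node payloads are broadcast to every leaf combination under the node, so
    each step's table is directly joinable with downstream steps on the full
    parameter assignment.
    """
    records = list(records)
    step_names = [s.name for s in pipeline.steps]
    for r in records:
        if r.step not in step_names:
            raise ValueError(f"record for unknown step {r.step!r}: mixed pipelines?")
    # reconstruct each leaf's full assignment from the deepest-level records
    tables: dict = {}
    all_params = pipeline.param_names
    leaf_map: dict = {}
    last_idx = len(pipeline.steps) - 1
    for r in records:
        if r.step_index == last_idx:
            for li in r.leaf_indices:
                leaf_map[(r.dataset, li)] = r.assignment
    for j, step in enumerate(pipeline.steps):
        rows = []
        for r in records:
            if r.step_index != j:
                continue
            for li in sorted(r.leaf_indices):
                full = leaf_map.get((r.dataset, li), r.assignment)
                row = {"dataset": r.dataset, "combination": li}
                for p in all_params:
                    row[p] = full.get(p, r.assignment.get(p, None))
                row["status"] = r.status
                row["elapsed"] = r.elapsed
                row.update(_flatten_payload(r.payload))
                rows.append(row)
        table = pd.DataFrame(rows)
        if not table.empty:
            table = table.sort_values(["dataset", "combination"], kind="stable")
            table = table.reset_index(drop=True)
        if step.aggregator is not None and not table.empty:
            table = step.aggregator(table)
        tables[step.name] = table
    return tables


class _ResumeLog:
    """Append-only JSON-lines record store keyed by (dataset, node_key)."""

    def __init__(self, path: str):
        self.path = path
        self.seen: dict = {}
        if os.path.exists(path):
            with open(path) as fh:
                for line in fh:
                    line = line.strip()
                    if not line:
                        continue
                    d = json.loads(line)
                    rec = RunRecord(
                        dataset=d["dataset"],
                        step=d["step"],
                        step_index=d["step_index"],
                        assignment=d["assignment"],
                        status=d["status"],
                        elapsed=d["elapsed"],
                        payload=d["payload"],
                        message=d.get("message", ""),
                        node_key=d["node_key"],
                        leaf_indices=d.get("leaf_indices", []),
                    )
                    self.seen[(rec.dataset, rec.node_key)] = rec
        self._fh = open(path, "a")

    def get(self, dataset: str, node_key: str) -> RunRecord | None:
        return self.seen.get((dataset, node_key))

    def append(self, rec: RunRecord) -> None:
        self._fh.write(rec.to_json() + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


def run_pipeline(
    pipeline: PipelineDefinition,
    alternatives: Mapping[str, Sequence],
    datasets: Mapping[str, Any],
    subset: Callable[[dict], bool] | Mapping[str, Sequence] | None = None,
    seed: int = 0,
    n_workers: int = 1,
    log_path: str | None = None,
    share_prefixes: bool = True,
) -> RunResults:
    """Run every parameter combination over every dataset.

    With ``share_prefixes`` (the default) each distinct pipeline prefix is
    executed exactly once per dataset, via depth-first traversal of the
    prefix tree; disabling it re-executes every combination from scratch
    (useful only as a correctness oracle). ``log_path`` enables the
    append-only resumability log. ``n_workers`` parallelizes over datasets;
    records are keyed, so the merge order is deterministic.
    """
    plan = enumerate_combinations(pipeline, alternatives, subset)
    roots = build_prefix_tree(plan, pipeline)
    log = _ResumeLog(log_path) if log_path else None

    def run_dataset(ds_id: str, raw: Any) -> list:
        records: list = []

        def record(rec: RunRecord) -> None:
            records.append(rec)
            if log is not None:
                log.append(rec)

        try:
            state0 = pipeline.initiator(raw) if pipeline.initiator else raw
        except Exception as exc:  # noqa: BLE001 - per-dataset isolation
            def mark_all(node: PrefixNode, status: str, msg: str) -> None:
                record(
                    RunRecord(
                        ds_id, pipeline.steps[node.step_index].name,
                        node.step_index, dict(node.assignment), status,
                        message=msg, node_key=node.key(),
                        leaf_indices=list(node.leaf_indices),
                    )
                )
                for c in node.children:
                    mark_all(c, "skipped", "upstream initiator error")
            for root in roots:
                mark_all(root, "error", f"initiator failed: {exc}")
            return records

        def mark_skipped(node: PrefixNode, msg: str) -> None:
            record(
                RunRecord(
                    ds_id, pipeline.steps[node.step_index].name, node.step_index,
                    dict(node.assignment), "skipped", message=msg,
                    node_key=node.key(), leaf_indices=list(node.leaf_indices),
                )
            )
            for c in node.children:
                mark_skipped(c, msg)

        def subtree_fully_recorded(node: PrefixNode) -> bool:
            if log is None or log.get(ds_id, node.key()) is None:
                return False
            return all(subtree_fully_recorded(c) for c in node.children)

        def visit(node: PrefixNode, state: Any) -> None:
            step = pipeline.steps[node.step_index]
            key = node.key()
            prior = log.get(ds_id, key) if log is not None else None
            if prior is not None:
                records.append(prior)
                if prior.status != "ok":
                    return
                if all(subtree_fully_recorded(c) for c in node.children):
                    for c in node.children:
                        replay(c)
                    return
            step_params = {p: node.assignment[p] for p in step.param_names}
            if _accepts_seed(step.operation, step.param_names):
                step_params["seed"] = node_seed(seed, ds_id, key)
            t0 = time.perf_counter()
            try:
                new_state = step.operation(state, **step_params)
            except Exception as exc:  # noqa: BLE001 - error isolation contract
                elapsed = time.perf_counter() - t0
                if prior is None:
                    record(
                        RunRecord(
                            ds_id, step.name, node.step_index,
                            dict(node.assignment), "error", elapsed,
                            message=str(exc), node_key=key,
                            leaf_indices=list(node.leaf_indices),
                        )
                    )
                for c in node.children:
                    mark_skipped(c, f"upstream error at {step.name}")
                return
            elapsed = time.perf_counter() - t0
            if prior is None:
                payload = None
                message = ""
                if step.evaluator is not None:
                    try:
                        payload = step.evaluator(new_state)
                    except Exception as exc:  # noqa: BLE001
                        payload = None
                        message = f"evaluator failed: {exc}"
                record(
                    RunRecord(
                        ds_id, step.name, node.step_index, dict(node.assignment),
                        "ok", elapsed, payload, message, key,
                        list(node.leaf_indices),
                    )
                )
            for c in node.children:
                visit(c, new_state)

        def replay(node: PrefixNode) -> None:
            prior = log.get(ds_id, node.key())
            records.append(prior)
            if prior.status != "ok":
                return
            for c in node.children:
                replay(c)

        if share_prefixes:
            for root in roots:
                visit(root, state0)
        else:
            # naive oracle: re-run every leaf from scratch, dedup by node key
            done: set = set()
            for li, combo in enumerate(plan):
                state = state0
                failed = False
                for j, step in enumerate(pipeline.steps):
                    assignment = {
                        p: combo[p]
                        for s in pipeline.steps[: j + 1]
                        for p in s.param_names
                    }
                    node = PrefixNode(j, assignment)
                    node.leaf_indices = [
                        i
                        for i, c in enumerate(plan)
                        if all(c[p] == assignment[p] for p in assignment)
                    ]
                    key = node.key()
                    step_params = {p: assignment[p] for p in step.param_names}
                    if _accepts_seed(step.operation, step.param_names):
                        step_params["seed"] = node_seed(seed, ds_id, key)
                    if failed:
                        if key not in done:
                            done.add(key)
                            record(
                                RunRecord(
                                    ds_id, step.name, j, assignment, "skipped",
                                    message="upstream error", node_key=key,
                                    leaf_indices=node.leaf_indices,
                                )
                            )
                        continue
                    t0 = time.perf_counter()
                    try:
                        state = step.operation(state, **step_params)
                    except Exception as exc:  # noqa: BLE001
                        failed = True
                        if key not in done:
                            done.add(key)
                            record(
                                RunRecord(
                                    ds_id, step.name, j, assignment, "error",
                                    time.perf_counter() - t0, message=str(exc),
                                    node_key=key, leaf_indices=node.leaf_indices,
                                )
                            )
                        continue
                    elapsed = time.perf_counter() - t0
                    if key not in done:
                        done.add(key)
                        payload = None
                        message = ""
                        if step.evaluator is not None:
                            try:
                                payload = step.evaluator(state)
                            except Exception as exc:  # noqa: BLE001
                                message = f"evaluator failed: {exc}"
                        record(
                            RunRecord(
                                ds_id, step.name, j, assignment, "ok", elapsed,
                                payload, message, key, node.leaf_indices,
                            )
                        )
        return records

    all_records: list = []
    items = list(datasets.items())
    if n_workers > 1 and len(items) > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=n_workers) as ex:
            futs = [ex.submit(run_dataset, ds_id, raw) for ds_id, raw in items]
            per_ds = [f.result() for f in futs]
    else:
        per_ds = [run_dataset(ds_id, raw) for ds_id, raw in items]
    for recs in per_ds:  # dataset submission order: deterministic merge
        all_records.extend(recs)
    if log is not None:
        log.close()
    return RunResults(pipeline, all_records)
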