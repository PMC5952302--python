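"""Batch orchestration of the protocol x intensity x sample grid."""

from __future__ import annotations

import dataclasses
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .analysis import RankSumResult, rank_sum_compare
from .engine import run_experiment
from .params import ExperimentConfig, canonical_protocol


@dataclass(frozen=True)
class BatchSpec:
    """Definition of a run grid: every (protocol, K, sample) tuple unique."""

    protocols: tuple[str, ...]
    K_values: tuple[float, ...]
    sample_ids: tuple[int, ...]
    base_config: ExperimentConfig = field(default_factory=ExperimentConfig)
    workers: int = 1

    def __post_init__(self):
        object.__setattr__(
            self, "protocols", tuple(canonical_protocol(p) for p in self.protocols)
        )
        cells = [(p, K, s) for p in self.protocols for K in self.K_values
                 for s in self.sample_ids]
        if len(set(cells)) != len(cells):
            raise ValueError("duplicate (protocol, K, sample) tuples in batch")

    def configs(self) -> list[ExperimentConfig]:
        return [
            dataclasses.replace(self.base_config, protocol=p, K=K, sample_id=s)
            for p in self.protocols
            for K in self.K_values
            for s in self.sample_ids
        ]


def _run_one(args):
    cfg, out_root = args
    run_dir = f"{cfg.protocol}_K{cfg.K:g}_s{cfg.sample_id}"
    try:
        result = run_experiment(cfg)
        files = io.save_result(result, Path(out_root) / run_dir) if out_root else {}
        row = io.run_summary(result)
        return {"run_dir": run_dir, "status": "ok", "files": files, "summary": row}
    except Exception as exc:  # failed runs are recorded, not fatal to the batch
        return {"run_dir": run_dir, "status": f"failed: {exc}", "files": {},
                "summary": None}


def run_batch(spec: BatchSpec, out_root=None) -> pd.DataFrame:
    """Execute the grid; write per-run outputs and a manifest under out_root.

    Returns the summary table (one row per successful run).  Raises after
    writing the manifest if any run failed.
    """
    jobs = [(cfg, out_root) for cfg in spec.configs()]
    if spec.workers > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=spec.workers) as pool:
            entries = list(pool.map(_run_one, jobs))
    else:
        entries = [_run_one(j) for j in jobs]

    rows = [e["summary"] for e in entries if e["summary"] is not None]
    summary = pd.DataFrame(rows)
    if out_root is not None:
        out_root = Path(out_root)
        out_root.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_root / "summary.csv", index=False)
        io.write_manifest(out_root, entries)
    failed = [e for e in entries if e["status"] != "ok"]
    if failed:
        names = ", ".join(e["run_dir"] for e in failed)
        raise RuntimeError(f"batch had failed runs: {names}")
    return summary


def compare_protocols(
    summary: pd.DataFrame,
    cell_a: tuple[str, float],
    cell_b: tuple[str, float],
    metric: str,
    side: str = "less",
    alpha: float = 0.05,
) -> dict:
    """Rank-sum comparison of one metric between two (protocol, K) cells."""
    def _cell(protocol, K):
        p = canonical_protocol(protocol)
        sub = summary[(summary["protocol"] == p) & (summary["K"] == K)]
        return sub[metric].to_numpy(float)

    a = _cell(*cell_a)
    b = _cell(*cell_b)
    if a.size == 0 or b.size == 0 or a.size != b.size:
        raise ValueError(
            f"unbalanced or empty cells: n_a={a.size}, n_b={b.size}"
        )
    res: RankSumResult = rank_sum_compare(a, b, side=side, alpha=alpha)
    return {
        "cell_a": {"protocol": canonical_protocol(cell_a[0]), "K": cell_a[1]},
        "cell_b": {"protocol": canonical_protocol(cell_b[0]), "K": cell_b[1]},
        "metric": metric,
        "side": side,
        "alpha": alpha,
        "n": int(a.size),
        "median_a": res.median_a,
        "median_b": res.median_b,
        "p_value": res.p_value,
        "significant": res.significant,
    }
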