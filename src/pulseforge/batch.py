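"""Batch execution: one shape file and one report per configured pulse."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .config import BatchConfig
from .optimize import OptimizationResult, horserace, optimize
from .shapes import save_shape
from .simulate import excitation_profile, make_report

__all__ = ["BatchItem", "BatchSummary", "run_batch"]

logger = logging.getLogger(__name__)


@dataclass
class BatchItem:
    name: str
    ok: bool
    infidelity: float | None = None
    seconds: float = 0.0
    shape_path: str | None = None
    report_path: str | None = None
    error: str | None = None
    result: OptimizationResult | None = None


@dataclass
class BatchSummary:
    items: list[BatchItem] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(it.ok for it in self.items)


def run_batch(config: BatchConfig, outdir) -> BatchSummary:
    """Design every pulse in the config; per-pulse failures are isolated.

    A pulse fails when its optimization errors out or its final infidelity
    exceeds the configured ``output.max_infidelity`` ceiling (if any).
    """
    out = Path(outdir if config.output.get("dir") is None else config.output["dir"])
    out.mkdir(parents=True, exist_ok=True)
    dialect = config.output.get("dialect", "bruker")
    write_report = bool(config.output.get("report", True))
    ceiling = config.output.get("max_infidelity")
    summary = BatchSummary()
    for job in config.jobs:
        t0 = time.perf_counter()
        item = BatchItem(name=job.name, ok=False)
        try:
            if config.optimizer.horserace is not None:
                result = horserace(job.spec, config.optimizer)
            else:
                result = optimize(job.spec, config.optimizer)
            item.result = result
            item.infidelity = result.infidelity
            ext = "jdx" if dialect == "bruker" else "RF"
            shape_path = out / f"{job.name}.{ext}"
            save_shape(result.pulse, shape_path, dialect=dialect, title=job.name)
            item.shape_path = str(shape_path)
            if write_report:
                report = make_report(result, excitation_profile(result.pulse))
                report_path = out / f"{job.name}.report.json"
                report.save(report_path)
                item.report_path = str(report_path)
            if ceiling is not None and result.infidelity > float(ceiling):
                item.error = (
                    f"final infidelity {result.infidelity:.3e} exceeds ceiling {ceiling}"
                )
            else:
                item.ok = True
        except Exception as err:  # isolate per-pulse failures, keep going
            item.error = str(err)
            logger.error("pulse %s failed: %s", job.name, err)
        item.seconds = time.perf_counter() - t0
        logger.info(
            "pulse %s: infidelity=%s in %.1f s (%s)",
            job.name,
            f"{item.infidelity:.3e}" if item.infidelity is not None else "n/a",
            item.seconds,
            "ok" if item.ok else f"FAILED: {item.error}",
        )
        summary.items.append(item)
    return summary
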