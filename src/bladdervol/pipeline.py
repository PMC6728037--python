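"""End-to-end batch pipeline over a pair manifest.

A manifest CSV row describes one procedure: ``id``,
``transverse_path``, ``longitudinal_path``, ``spacing_mm_per_px`` and
optionally ``actual_volume_ml``.  The pipeline reads both frames, runs
segmentation + measurement + the ellipsoid formula, classifies against
the configured thresholds and, when actual volumes are present, adds
the agreement/accuracy report.  Per-row failures are flagged in the
results, not fatal to the run.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import pandas as pd

from . import evaluation, io
from .frames import LONGITUDINAL, TRANSVERSE, NoBladderDetected
from .geometry import HORIZONTAL_TOLERANCE_DEG, ORTHOGONAL_TOLERANCE_DEG
from .volume import ELLIPSOID_COEFFICIENT, classify, estimate_pair

logger = logging.getLogger("bladdervol")


@dataclass
class PipelineConfig:
    """Run-wide settings for the automated pipeline."""

    backend: str = "classical"
    mode: str = "chord"
    thresholds_ml: Tuple[float, ...] = (50.0, 100.0)
    horizontal_tolerance_deg: float = HORIZONTAL_TOLERANCE_DEG
    orthogonal_tolerance_deg: float = ORTHOGONAL_TOLERANCE_DEG
    ellipsoid_coefficient: float = ELLIPSOID_COEFFICIENT
    seed: int = 0
    segmenter: Optional[object] = field(default=None, repr=False)

    def __post_init__(self):
        if any(t <= 0 for t in self.thresholds_ml):
            raise ValueError("thresholds must be positive")
        if list(self.thresholds_ml) != sorted(self.thresholds_ml):
            raise ValueError("thresholds must be sorted ascending")
        for tol in (self.horizontal_tolerance_deg, self.orthogonal_tolerance_deg):
            if not 0.0 < tol <= 45.0:
                raise ValueError("angle tolerances must lie in (0, 45]")


def run_pipeline(
    manifest, config: Optional[PipelineConfig] = None
) -> Tuple[pd.DataFrame, Optional[evaluation.EvaluationReport]]:
    """Process every manifest row; returns (results, optional report).

    ``manifest`` is a DataFrame or a CSV path.  Results carry one row
    per input pair with the three diameters (cm), the volume (ml), the
    classification at each threshold, backend/mode provenance and a
    ``status`` column ("ok" or the failure reason).
    """
    if config is None:
        config = PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)

    rows: List[dict] = []
    volume_pairs = []
    for _, rec in manifest.iterrows():
        row = {
            "id": rec["id"],
            "a_cm": float("nan"),
            "b_cm": float("nan"),
            "c_cm": float("nan"),
            "volume_ml": float("nan"),
            "backend": config.backend,
            "mode": config.mode,
            "status": "ok",
        }
        for thr in config.thresholds_ml:
            row[f"class_{int(thr)}"] = ""
        t0 = time.perf_counter()
        try:
            spacing = float(rec["spacing_mm_per_px"])
            t_frame = io.read_frame(rec["transverse_path"], TRANSVERSE, spacing)
            l_frame = io.read_frame(rec["longitudinal_path"], LONGITUDINAL, spacing)
            est = estimate_pair(
                t_frame,
                l_frame,
                backend=config.backend,
                mode=config.mode,
                segmenter=config.segmenter,
                coefficient=config.ellipsoid_coefficient,
                horizontal_tolerance_deg=config.horizontal_tolerance_deg,
                orthogonal_tolerance_deg=config.orthogonal_tolerance_deg,
            )
            d = est.diameters
            row.update(a_cm=d.a_cm, b_cm=d.b_cm, c_cm=d.c_cm, volume_ml=est.volume_ml)
            for thr in config.thresholds_ml:
                row[f"class_{int(thr)}"] = classify(est, thr)
            logger.info(
                "pair %s: a=%.2f cm (%.1f mm) b=%.2f cm (%.1f mm) c=%.2f cm (%.1f mm) "
                "V=%.1f ml [%.2f s]",
                rec["id"], d.a_cm, d.a_cm * 10, d.b_cm, d.b_cm * 10, d.c_cm, d.c_cm * 10,
                est.volume_ml, time.perf_counter() - t0,
            )
            if "actual_volume_ml" in rec and pd.notna(rec["actual_volume_ml"]):
                volume_pairs.append((est.volume_ml, float(rec["actual_volume_ml"])))
        except (NoBladderDetected, FileNotFoundError, ValueError, OSError) as exc:
            row["status"] = f"failed: {exc}"
            logger.warning("pair %s failed: %s", rec["id"], exc)
        rows.append(row)

    results = pd.DataFrame(rows)
    report = None
    if len(volume_pairs) >= 2:
        report = evaluation.evaluate(volume_pairs, thresholds_ml=config.thresholds_ml)
    return results, report
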