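"""Batch run reports: per-image rows and aggregate error statistics."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["ImageRecord", "RunReport", "ERROR_BINS"]

#: Upper edges of the absolute-error bins (cm); the last bin is open-ended.
ERROR_BINS = (0.1, 0.2, 0.3)
_BIN_NAMES = ("<0.1", "<0.2", "<0.3", ">=0.3")


def error_bin(abs_error_cm: float) -> str:
    for edge, name in zip(ERROR_BINS, _BIN_NAMES):
        if abs_error_cm < edge:
            return name
    return _BIN_NAMES[-1]


@dataclass
class ImageRecord:
    filename: str
    success: bool
    stage_failed: str | None = None
    thickness_cm: float | None = None
    truth_cm: float | None = None

    @property
    def abs_error_cm(self) -> float | None:
        if self.thickness_cm is None or self.truth_cm is None:
            return None
        return abs(self.thickness_cm - self.truth_cm)

    @property
    def error_bin(self) -> str | None:
        e = self.abs_error_cm
        return None if e is None else error_bin(e)


@dataclass
class RunReport:
    records: list[ImageRecord] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def n_images(self) -> int:
        return len(self.records)

    @property
    def n_success(self) -> int:
        return sum(r.success for r in self.records)

    @property
    def success_rate(self) -> float:
        return self.n_success / self.n_images if self.records else 0.0

    def error_histogram(self) -> dict[str, int]:
        hist = {name: 0 for name in _BIN_NAMES}
        for r in self.records:
            b = r.error_bin
            if b is not None:
                hist[b] += 1
        return hist

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as f:
            wr = csv.writer(f)
            wr.writerow(["filename", "success", "stage_failed", "thickness_cm",
                         "truth_cm", "abs_error_cm", "error_bin"])
            for r in sorted(self.records, key=lambda r: r.filename):
                err = r.abs_error_cm
                wr.writerow([
                    r.filename, int(r.success), r.stage_failed or "",
                    f"{r.thickness_cm:.4f}" if r.thickness_cm is not None else "",
                    f"{r.truth_cm:.4f}" if r.truth_cm is not None else "",
                    f"{err:.4f}" if err is not None else "",
                    r.error_bin or "",
                ])

    def write_json(self, path: str | Path) -> None:
        payload = {
            "n_images": self.n_images,
            "n_success": self.n_success,
            "success_rate": self.success_rate,
            "error_histogram": self.error_histogram(),
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, indent=1))
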