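"""In-memory containers for multi-subject ROI time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CohortTimeSeries"]


@dataclass
class CohortTimeSeries:
    """A cohort of region-of-interest signals: ``data[s, i, t]`` is subject
    ``s``'s signal in region ``i`` at timepoint ``t``.

    Every subject shares the same regions and recording length; all values
    must be finite.
    """

    data: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"cohort data must be 3-D (m, n, t), got {self.data.shape}")
        m, n, _ = self.data.shape
        if not self.subject_ids:
            self.subject_ids = [f"sub-{s + 1:03d}" for s in range(m)]
        if not self.region_labels:
            self.region_labels = [f"roi-{i + 1}" for i in range(n)]
        if len(self.subject_ids) != m:
            raise ValueError("subject_ids length must match the subject axis")
        if len(self.region_labels) != n:
            raise ValueError("region_labels length must match the region axis")
        bad = np.argwhere(~np.isfinite(self.data))
        if bad.size:
            s, i, t = bad[0]
            raise ValueError(
                f"non-finite value for subject {self.subject_ids[s]!r}, "
                f"region {self.region_labels[i]!r} at timepoint {t}"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    def subject(self, s: int) -> np.ndarray:
        """The (n, t) matrix of one subject."""
        return self.data[s]

    def zscore(self) -> "CohortTimeSeries":
        """Per-subject, per-region standardization over time.

        Regions with zero temporal variance are left centred at zero rather
        than divided by zero.
        """
        mu = self.data.mean(axis=2, keepdims=True)
        sd = self.data.std(axis=2, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        return CohortTimeSeries(
            (self.data - mu) / sd, list(self.subject_ids), list(self.region_labels)
        )
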