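"""Run configuration shared by every pipeline stage.

All tunables of the embedding pipeline live in a single :class:`RunConfig`
so that a whole analysis is reproducible from one small JSON document plus
one integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Union

#: Metrics handled by the pipeline, in canonical block order.
METRICS = ("volume", "thickness", "area")

#: Which global covariate corrects each metric for overall scale.
METRIC_COVARIATE = {
    "volume": "icv",
    "thickness": "mean_thickness",
    "area": "total_area",
}

Bandwidth = Union[float, str]  # a positive float, or "auto"


@dataclass
class RunConfig:
    """Configuration of a supervised-NPE analysis.

    Parameters
    ----------
    k
        Neighbours per subject in the supervised graph (default 10).
    d
        Manifold dimensions per metric (default 3).
    variance_retained
        Fraction of variance kept by the per-metric SVD reduction
        (default 0.95).
    n_folds
        Cross-validation folds (default 10).
    use_site_constraint
        Zero image similarity between same-site subject pairs, so
        neighbourhoods span acquisition sites.
    global_scale_correction
        Residualize each metric's features against its global covariate
        (intracranial volume / total surface area / mean cortical
        thickness) before embedding.
    age_bandwidth, image_bandwidth
        Gaussian-kernel bandwidths tau (years) and sigma; ``"auto"``
        selects the median heuristic.
    combination_mode
        ``"product"`` multiplies image and age similarity; ``"weighted_sum"``
        uses ``weight_lambda * image + (1 - weight_lambda) * age`` with the
        image-side masks re-applied.
    scale_correction_method
        ``"residual"`` (per-feature OLS residualization, default) or
        ``"ratio"`` (divide features by covariate / its training mean),
        exposed for sensitivity analysis.
    metrics
        Metric blocks to include; single-metric ablations are expressed by
        restricting this tuple, there is no special code path.
    """

    k: int = 10
    d: int = 3
    variance_retained: float = 0.95
    n_folds: int = 10
    use_site_constraint: bool = True
    global_scale_correction: bool = False
    age_bandwidth: Bandwidth = "auto"
    image_bandwidth: Bandwidth = "auto"
    combination_mode: str = "product"
    weight_lambda: float = 0.5
    scale_correction_method: str = "residual"
    stratified_folds: bool = True
    metrics: tuple = METRICS
    gp_restarts: int = 3
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not (1 <= self.d <= self.k):
            raise ValueError(f"d must satisfy 1 <= d <= k={self.k}, got {self.d}")
        if not (0.0 < self.variance_retained <= 1.0):
            raise ValueError(
                f"variance_retained must be in (0, 1], got {self.variance_retained}"
            )
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.combination_mode not in ("product", "weighted_sum"):
            raise ValueError(f"unknown combination_mode {self.combination_mode!r}")
        if not (0.0 <= self.weight_lambda <= 1.0):
            raise ValueError(f"weight_lambda must be in [0, 1], got {self.weight_lambda}")
        if self.scale_correction_method not in ("residual", "ratio"):
            raise ValueError(
                f"unknown scale_correction_method {self.scale_correction_method!r}"
            )
        for bw_name in ("age_bandwidth", "image_bandwidth"):
            bw = getattr(self, bw_name)
            if isinstance(bw, str):
                if bw != "auto":
                    raise ValueError(f"{bw_name} must be positive or 'auto', got {bw!r}")
            elif not bw > 0:
                raise ValueError(f"{bw_name} must be positive, got {bw}")
        self.metrics = tuple(self.metrics)
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown metrics {sorted(unknown)}; valid: {METRICS}")
        if not self.metrics:
            raise ValueError("at least one metric is required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["metrics"] = list(self.metrics)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys {sorted(extra)}")
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
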