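"""Fusion schemes combining bottom-up saliency with the center-bias prior.

Four pointwise schemes are supported for ``SP = f(SC, SB)``:

- ``convex``:  ``wC * SC + wB * SB`` with ``wB = 1 - wC`` (the default
  integration scheme);
- ``product``: Hadamard product ``SC * SB`` (supra-linear);
- ``min``:     pointwise minimum, optionally of the weighted inputs
  ``min(wC * SC, wB * SB)`` (supra-linear);
- ``max``:     pointwise maximum, optionally weighted (sub-linear / late).

Inputs are expected in [0, 1].  ``combine`` returns the raw fused values;
threshold-sweep evaluation is invariant to min-max rescaling, so any
renormalization is cosmetic and left to the caller (map export does it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FusionSpec", "SCHEMES", "combine", "sweep_wc"]

SCHEMES = ("convex", "product", "min", "max")


@dataclass(frozen=True)
class FusionSpec:
    """Scheme + center-bias weight; ``wb`` is always ``1 - wc``."""

    scheme: str = "convex"
    wc: float = 0.5
    weighted_extrema: bool = False

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown fusion scheme {self.scheme!r}; choose from {SCHEMES}")
        if not 0.0 <= self.wc <= 1.0:
            raise ValueError("wc must lie in [0, 1]")

    @property
    def wb(self) -> float:
        return 1.0 - self.wc


def combine(sc, sb, spec: FusionSpec | None = None, *, scheme: str | None = None,
            wc: float | None = None, weighted_extrema: bool | None = None) -> np.ndarray:
    """Fuse a center-bias map/score ``sc`` with a bottom-up one ``sb``.

    Accepts either a :class:`FusionSpec` or the individual keywords.
    Works on full maps and on per-region score vectors alike.
    """
    if spec is None:
        spec = FusionSpec(
            scheme=scheme or "convex",
            wc=0.5 if wc is None else wc,
            weighted_extrema=bool(weighted_extrema),
        )
    elif scheme is not None or wc is not None or weighted_extrema is not None:
        raise TypeError("pass either a FusionSpec or keywords, not both")
    sc = np.asarray(sc, dtype=float)
    sb = np.asarray(sb, dtype=float)
    if sc.shape != sb.shape:
        raise ValueError(f"shape mismatch: {sc.shape} vs {sb.shape}")
    for name, arr in (("SC", sc), ("SB", sb)):
        if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
            raise ValueError(f"{name} must be normalized to [0, 1]")
    if spec.scheme == "convex":
        return spec.wc * sc + spec.wb * sb
    if spec.scheme == "product":
        return sc * sb
    a, b = (spec.wc * sc, spec.wb * sb) if spec.weighted_extrema else (sc, sb)
    if spec.scheme == "min":
        return np.minimum(a, b)
    return np.maximum(a, b)


def sweep_wc(sc_maps, sb_maps, masks, scheme: str = "convex", step: float = 0.025,
             weighted_extrema: bool = False, **eval_kwargs):
    """Evaluation measures as a function of the center-bias weight.

    Fuses each (SC, SB) pair under ``scheme`` at every ``wc`` on a grid
    from 0 to 1 in ``step`` increments (41 rows at the default step) and
    evaluates against the masks.  The first row (wc = 0, convex) is the
    unbiased algorithm; the last (wc = 1, convex) the standalone center
    bias.

    Returns a pandas DataFrame with columns wc, f1, fbeta, pr_auc,
    roc_auc, hit_rate.
    """
    from .evaluation import evaluate_dataset

    n_steps = round(1.0 / step)
    if abs(n_steps * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1 evenly")
    rows = []
    for wc in np.linspace(0.0, 1.0, n_steps + 1):
        spec = FusionSpec(scheme, float(wc), weighted_extrema)
        fused = [combine(sc, sb, spec) for sc, sb in zip(sc_maps, sb_maps)]
        scores = evaluate_dataset(fused, masks, **eval_kwargs)
        rows.append(
            {
                "wc": float(wc),
                "f1": scores.f1,
                "fbeta": scores.fbeta,
                "pr_auc": scores.pr_auc,
                "roc_auc": scores.roc_auc,
                "hit_rate": scores.hit_rate,
            }
        )
    import pandas as pd

    return pd.DataFrame(rows)
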