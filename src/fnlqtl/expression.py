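"""Relative gene expression by the 2^−ΔΔCt (Livak) method.

Technical replicates are averaged on the Ct (cycle) scale; per sample,
ΔCt = mean Ct(target) − mean Ct(reference), ΔΔCt subtracts the calibrator's
ΔCt, and the fold change is 2^−ΔΔCt with amplification efficiency fixed at 2.
Replicate SDs propagate to ΔCt as sqrt(sd_target² + sd_reference²).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["relative_expression"]


def relative_expression(
    measurements: pd.DataFrame,
    calibrator: str,
    reference_gene: str = "reference",
    target_gene: str | None = None,
) -> pd.DataFrame:
    """2^−ΔΔCt fold changes per sample from a long-format Ct table.

    ``measurements`` needs columns sample, gene, ct (replicate rows repeat
    the sample/gene pair).  The calibrator sample's fold change is exactly 1.
    Returns a table indexed by sample with delta_ct, sd_delta_ct,
    delta_delta_ct and fold_change.
    """
    df = measurements.copy()
    for col in ("sample", "gene", "ct"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    genes = set(df["gene"])
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} absent")
    if target_gene is None:
        others = genes - {reference_gene}
        if len(others) != 1:
            raise ValueError(
                f"cannot infer target gene among {sorted(others)}; pass target_gene"
            )
        target_gene = others.pop()

    stats = (
        df.groupby(["sample", "gene"])["ct"]
        .agg(["mean", "std", "count"])
        .fillna({"std": 0.0})
    )
    samples = df["sample"].unique()
    if calibrator not in samples:
        raise ValueError(f"calibrator sample {calibrator!r} absent")
    rows = {}
    for s in samples:
        for g in (target_gene, reference_gene):
            if (s, g) not in stats.index:
                raise ValueError(f"sample {s!r} lacks measurements for {g!r}")
        t = stats.loc[(s, target_gene)]
        r = stats.loc[(s, reference_gene)]
        rows[s] = (
            float(t["mean"] - r["mean"]),
            float(np.sqrt(t["std"] ** 2 + r["std"] ** 2)),
        )
    cal_dct = rows[calibrator][0]
    out = pd.DataFrame(
        {
            "delta_ct": {s: v[0] for s, v in rows.items()},
            "sd_delta_ct": {s: v[1] for s, v in rows.items()},
        }
    )
    out["delta_delta_ct"] = out["delta_ct"] - cal_dct
    out["fold_change"] = 2.0 ** (-out["delta_delta_ct"])
    out.index.name = "sample"
    return out.loc[list(samples)]
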