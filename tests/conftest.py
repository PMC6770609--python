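"""Shared fixtures: tiny catalogs, hand-made call matrices and DE tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bcngdose import ArmCallMatrix, DEResult, RegionCatalog
from bcngdose.genome import ARM, WHOLE, Region


@pytest.fixture
def toy_catalog() -> RegionCatalog:
    """Two arm chromosomes (c1, c2) plus one acrocentric (c3)."""
    return RegionCatalog.from_layout("toy-5")


@pytest.fixture
def flat_catalog() -> RegionCatalog:
    """Small hand-built catalog with round lengths for fraction arithmetic."""
    return RegionCatalog(
        [
            Region("8p", "8", 0, 1000, ARM),
            Region("8q", "8", 1000, 3000, ARM),
            Region("13", "13", 0, 1500, WHOLE),
        ]
    )


def make_calls(catalog: RegionCatalog, rows: dict[str, dict[str, str]]) -> ArmCallMatrix:
    """Build an ArmCallMatrix from {sample: {region: call}} (rest neutral)."""
    df = pd.DataFrame("neutral", index=list(rows), columns=catalog.region_ids)
    for sample, calls in rows.items():
        for region, call in calls.items():
            df.loc[sample, region] = call
    df.index.name = "sample"
    return ArmCallMatrix(calls=df, catalog=catalog)


def make_de(contrast: str, entries: dict[str, tuple[float, float]]) -> DEResult:
    """DEResult from {transcript: (signed_fc, fdr)}; p-value set equal to FDR."""
    signed = np.array([v[0] for v in entries.values()], dtype=float)
    fdr = np.array([v[1] for v in entries.values()], dtype=float)
    log2fc = np.where(signed >= 1, 1.0, -1.0) * np.log2(np.abs(signed))
    table = pd.DataFrame(
        {
            "mean_cpm": 100.0,
            "log2_fc": log2fc,
            "signed_fc": signed,
            "pvalue": fdr,
            "fdr": fdr,
        },
        index=pd.Index(list(entries), name="transcript"),
    )
    return DEResult(contrast=contrast, table=table)


@pytest.fixture
def seg_row():
    def _row(sample, chrom, start, end, cn):
        return {"sample": sample, "chromosome": chrom, "start": start, "end": end,
                "copy_number": cn}
    return _row
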