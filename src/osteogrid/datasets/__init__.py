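"""Bundled reference tables.

``capitate_rma_table``: published reduced-major-axis regression summaries
(slope, 95% CI, r², intercept, p, assigned allometry category) of seven
whole-bone parameters against logged cube-root capitate volume, for a
comparative hominoid sample as a whole and within each of four genera.
Used to validate the allometry-classification rules against independently
published fits.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_capitate_rma_table"]


def _numeric(series: pd.Series) -> pd.Series:
    """Parse printed values where '<x' means 'below the printed precision'."""
    def conv(v):
        s = str(v).strip()
        if s.startswith("<"):
            return float(s[1:]) / 2.0
        return float(s)
    return series.map(conv)


def load_capitate_rma_table() -> pd.DataFrame:
    """Published RMA summaries with numeric helper columns ``p_num``/``r2_num``."""
    with resources.files(__package__).joinpath("capitate_rma_table.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"p": str, "r2": str})
    df["p_num"] = _numeric(df["p"])
    df["r2_num"] = _numeric(df["r2"])
    df["isometric_slope"] = df["isometric_slope"].astype(int)
    for c in ("slope", "ci_low", "ci_high", "intercept"):
        df[c] = df[c].astype(float)
    assert len(df) == 35
    assert not df.isna().any().any()
    return df
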