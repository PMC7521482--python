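"""Plain-text input/output for panels, truth tables and weight targets."""

from __future__ import annotations

import pandas as pd


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    """Read a long-format panel CSV (subject_id, age, state, is_death_record,
    covariates); empty state cells become missing living states."""
    df = pd.read_csv(path)
    df["state"] = pd.to_numeric(df["state"], errors="coerce")
    df["is_death_record"] = df["is_death_record"].astype(int)
    return df


def read_target_distribution(path) -> pd.DataFrame:
    """Read a post-stratification target table
    (columns age_band, sex, residence, proportion)."""
    df = pd.read_csv(path)
    required = {"age_band", "sex", "residence", "proportion"}
    if required - set(df.columns):
        raise ValueError(f"target table missing columns: {sorted(required - set(df.columns))}")
    return df
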