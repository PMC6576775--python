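"""CSV report writers: ranking tables, estimate tables, averaged detection.

Output dialect: comma delimiter, "." decimal, NA for missing values.
Probabilities are rounded to 2 decimals and the derived daily detection
(theta * p) to 3, matching standard report precision.
"""

from __future__ import annotations

import pandas as pd

from .selection import ModelRanking


def ranking_frame(ranking: ModelRanking, ndigits: int = 2) -> pd.DataFrame:
    df = ranking.table.copy()
    df["loglik"] = df["loglik"].round(3)
    df["AICc"] = df["AICc"].round(2)
    df["dAICc"] = df["dAICc"].round(2)
    df["weight"] = df["weight"].round(2)
    return df


def write_ranking_csv(ranking: ModelRanking, path) -> None:
    ranking_frame(ranking).to_csv(path, index=False, na_rep="NA")


def write_estimates_csv(estimates: pd.DataFrame, path) -> None:
    """Write an estimate table (psi/theta/p and theta*p per method)."""
    df = estimates.copy()
    for col in ("psi", "psi_se", "theta", "theta_se", "p", "p_se"):
        df[col] = df[col].round(2)
    df["theta_p"] = df["theta_p"].round(3)
    df.to_csv(path, index=False, na_rep="NA")


def write_averaged_csv(averaged: pd.DataFrame, path) -> None:
    """Write model-averaged detection estimates (method x estimate x SE)."""
    df = averaged.copy()
    df["estimate"] = df["estimate"].round(3)
    df["se"] = df["se"].round(3)
    df.to_csv(path, na_rep="NA")
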