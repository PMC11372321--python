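"""Packaged worked-example tables from the published study.

Eight group-metric tables (default-threshold audits and post-mitigation
results for the SGD- and Adam-trained networks, before and after 1-N
matching), the two neural-network confusion-count sets, and the matching
balance table. These are inputs for worked-example checks — the disparity,
improvement and weight computations reproduce their printed summary cells
— not outputs of this package.
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

from .metrics import ConfusionCounts

__all__ = ["GROUP_TABLE_IDS", "load_fixture_tables", "load_balance_table"]

GROUP_TABLE_IDS = tuple(f"table{i}" for i in range(3, 11))

#: Which mitigation table pairs with which default-threshold table
#: (same model and test set; mitigation changes only the threshold).
MITIGATION_PAIRS = {
    "table7": "table3",
    "table8": "table4",
    "table9": "table5",
    "table10": "table6",
}


def _read_csv(name: str) -> pd.DataFrame:
    text = resources.files("fairmove.data").joinpath(name).read_text()
    return pd.read_csv(io.StringIO(text))


def load_fixture_tables() -> dict:
    """Return all packaged tables keyed by table id.

    Each group table maps attribute -> {"a": metrics, "b": metrics,
    "difference": float, "optimal_threshold": float | None}; metric dicts
    hold recall/specificity/accuracy and, where printed, auc (percent).
    Confusion-count sets appear under "confusion_nn_sgd" and
    "confusion_nn_adam"; the balance table under "table2_balance".
    """
    out: dict = {}
    for tid in GROUP_TABLE_IDS:
        frame = _read_csv(f"{tid}.csv")
        table: dict = {}
        for attr, sub in frame.groupby("attribute", sort=False):
            entry: dict = {
                "difference": float(sub["difference"].iloc[0]),
                "optimal_threshold": None
                if sub["optimal_threshold"].isna().all()
                else float(sub["optimal_threshold"].iloc[0]),
            }
            for _, row in sub.iterrows():
                metrics = {
                    "recall": float(row["recall"]),
                    "specificity": float(row["specificity"]),
                    "accuracy": float(row["accuracy"]),
                }
                if pd.notna(row.get("auc")):
                    metrics["auc"] = float(row["auc"])
                entry[row["group"]] = metrics
            table[attr] = entry
        out[tid] = table
    for _, row in _read_csv("confusion.csv").iterrows():
        out[f"confusion_{row['model']}"] = ConfusionCounts(
            tp=int(row["tp"]), fn=int(row["fn"]), fp=int(row["fp"]), tn=int(row["tn"])
        )
    out["table2_balance"] = load_balance_table()
    return out


def load_balance_table() -> pd.DataFrame:
    """The published SMD / variance-ratio rows before and after matching."""
    return _read_csv("table2_balance.csv")
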