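"""CSV schemas for all pipeline inputs and outputs.

All files are UTF-8 comma-separated with a header row; missing values are
empty fields.  Schemas:

- trials.csv: trial_id, condition, line_a, line_b, mated_line (empty = none)
- receptivity.csv: line, male_line, individual, minutes, censored
- traits.csv: line, individual, mass_mg, chc_1..chc_29
- offspring.csv: line, male_line, individual, count
- proximity.csv: trial_id, line_plus, line_minus, t_plus_s, t_minus_s, replicate
- network.csv: line_i, line_j, wins_ij, wins_ji, p_ij, orientation
- ranking.csv: line, score, rank
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .network import ChoiceNetwork, Ranking, WinMatrix

__all__ = [
    "read_trials",
    "write_trials",
    "read_receptivity",
    "read_offspring",
    "read_proximity",
    "read_traits",
    "write_network",
    "read_network",
    "write_ranking",
    "SchemaError",
]


class SchemaError(ValueError):
    """An input table does not match its documented schema."""


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require(df, ["trial_id", "condition", "line_a", "line_b", "mated_line"], path)
    bad = df[
        (df["mated_line"] != "")
        & (df["mated_line"] != df["line_a"])
        & (df["mated_line"] != df["line_b"])
    ]
    if not bad.empty:
        raise SchemaError(
            f"{path}: {len(bad)} rows with mated_line outside the trial pair "
            f"(first offending trial_id: {bad.iloc[0]['trial_id']})"
        )
    same = df[df["line_a"] == df["line_b"]]
    if not same.empty:
        raise SchemaError(f"{path}: {len(same)} rows with line_a == line_b")
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_receptivity(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["line", "individual", "minutes", "censored"], path)
    if "male_line" not in df:
        df["male_line"] = "all"
    df["censored"] = df["censored"].astype(bool)
    if (df["minutes"] <= 0).any():
        raise SchemaError(f"{path}: non-positive minutes")
    return df


def read_offspring(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["line", "male_line", "individual", "count"], path)
    if (df["count"] < 0).any() or not np.issubdtype(df["count"].dtype, np.integer):
        raise SchemaError(f"{path}: counts must be nonnegative integers")
    return df


def read_proximity(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["trial_id", "line_plus", "line_minus", "t_plus_s", "t_minus_s"], path)
    if "replicate" not in df:
        df["replicate"] = "r1"
    if (df[["t_plus_s", "t_minus_s"]] < 0).any().any():
        raise SchemaError(f"{path}: negative dwell times")
    return df


def read_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["line", "individual", "mass_mg"], path)
    chc_cols = [c for c in df.columns if c.startswith("chc_")]
    if chc_cols:
        sums = df[chc_cols].sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise SchemaError(f"{path}: CHC relative abundances must sum to 1 per row")
    return df


def write_network(net: ChoiceNetwork, path: str | Path, wins: WinMatrix | None = None) -> None:
    rows = []
    for a, b in combinations(sorted(net.lines), 2):
        p = net.pref.loc[a, b]
        w = net.orientation(a, b)
        orient = "tie" if w is None else (f"{a}>{b}" if w == a else f"{b}>{a}")
        if (a, b) in net.no_data:
            orient = "no_data"
        wab = wba = ""
        src = wins.wins if wins is not None else net.wins
        if src is not None:
            wab, wba = int(src.loc[a, b]), int(src.loc[b, a])
        rows.append(
            {
                "line_i": a,
                "line_j": b,
                "wins_ij": wab,
                "wins_ji": wba,
                "p_ij": "" if pd.isna(p) else p,
                "orientation": orient,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_network(path: str | Path) -> ChoiceNetwork:
    df = pd.read_csv(path, keep_default_na=False)
    _require(df, ["line_i", "line_j", "p_ij", "orientation"], path)
    pref = {}
    no_data = set()
    for _, row in df.iterrows():
        pair = (str(row["line_i"]), str(row["line_j"]))
        p = row["p_ij"]
        pref[pair] = float(p) if p != "" else None
        if row["orientation"] == "no_data":
            no_data.add(pair)
    net = ChoiceNetwork.from_preferences({k: v for k, v in pref.items() if v is not None})
    # make sure lines that only appear in undefined pairs are kept
    lines = sorted({l for pair in pref for l in pair})
    if set(lines) != set(net.lines):
        mat = pd.DataFrame(np.nan, index=lines, columns=lines)
        mat.loc[net.pref.index, net.pref.columns] = net.pref
        net = ChoiceNetwork(lines, mat)
    net.no_data = no_data
    return net


def write_ranking(ranking: Ranking, path: str | Path) -> None:
    ranking.table.to_csv(path, index=False)
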