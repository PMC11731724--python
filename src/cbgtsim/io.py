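"""Result assembly, serialization and task-level data frames.

Results are stored open-format: CSV for tables, JSON for configuration and
metadata, either as a directory or a single ``.zip`` archive.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .core import ConfigError
from .sim import ResultsBundle

__all__ = ["save_results", "load_results", "extract_frames", "ExtractedFrames", "ResultsIOError"]


class ResultsIOError(RuntimeError):
    """Structured load/save failure (missing, corrupt or unknown content)."""


_TABLE_KEYS = ("popfreqs", "datatables", "Q_df", "reward_schedule")


def _available_tables(results: ResultsBundle) -> dict[str, pd.DataFrame]:
    tables = {k: results[k] for k in _TABLE_KEYS if k in results}
    for name, df in results.get("recorded_variables", {}).items():
        tables[name] = df
    return tables


def save_results(
    results: ResultsBundle | Sequence[ResultsBundle],
    path: str | Path,
    tables: Sequence[str] | None = None,
) -> Path:
    """Write a results bundle (or list of bundles) to ``path``.

    ``path`` ending in ``.zip`` produces a single archive; otherwise a
    directory is created.  ``tables`` restricts which tables are written
    (metadata is always included); an unknown name raises an error listing
    the available tables.
    """
    bundles = [results] if isinstance(results, dict) else list(results)
    path = Path(path)
    files: dict[str, str] = {}
    for i, bundle in enumerate(bundles):
        prefix = "" if len(bundles) == 1 else f"sim{i}/"
        avail = _available_tables(bundle)
        chosen = list(avail) if tables is None else list(tables)
        for name in chosen:
            if name not in avail:
                raise ConfigError(
                    f"unknown table {name!r}; available: {sorted(avail)}"
                )
            files[f"{prefix}{name}.csv"] = avail[name].to_csv(index=False)
        meta = {
            k: v
            for k, v in bundle.items()
            if not isinstance(v, pd.DataFrame) and k != "recorded_variables"
        }
        meta["tables"] = chosen
        meta["n_sims"] = len(bundles)
        files[f"{prefix}metadata.json"] = json.dumps(meta, indent=1, default=_json_default)

    if path.suffix == ".zip":
        path.parent.mkdir(parents=True, exist_ok=True)
        with zipfile.ZipFile(path, "w") as zf:
            for name, text in files.items():
                zf.writestr(name, text)
    else:
        for name, text in files.items():
            target = path / name
            target.parent.mkdir(parents=True, exist_ok=True)
            target.write_text(text)
    return path


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_results(path: str | Path) -> ResultsBundle | list[ResultsBundle]:
    """Load results saved by :func:`save_results` (directory or .zip).

    Round-trips every saved table bit-exactly.  Corrupt or missing content
    raises :class:`ResultsIOError`.
    """
    path = Path(path)
    try:
        if path.suffix == ".zip":
            with zipfile.ZipFile(path) as zf:
                files = {n: zf.read(n).decode() for n in zf.namelist()}
        elif path.is_dir():
            files = {
                str(p.relative_to(path)): p.read_text()
                for p in path.rglob("*")
                if p.is_file()
            }
        else:
            raise ResultsIOError(f"no results at {path}")
    except (zipfile.BadZipFile, OSError) as exc:
        raise ResultsIOError(f"cannot read results archive {path}: {exc}") from exc

    prefixes = sorted({n.split("/", 1)[0] + "/" for n in files if "/" in n}) or [""]
    if "metadata.json" in files:
        prefixes = [""]
    bundles = []
    for prefix in prefixes:
        meta_name = f"{prefix}metadata.json"
        if meta_name not in files:
            raise ResultsIOError(f"results at {path} lack {meta_name}")
        try:
            meta = json.loads(files[meta_name])
        except json.JSONDecodeError as exc:
            raise ResultsIOError(f"corrupt metadata in {path}: {exc}") from exc
        bundle = ResultsBundle(meta)
        recorded = {}
        for name in meta.get("tables", []):
            csv_name = f"{prefix}{name}.csv"
            if csv_name not in files:
                raise ResultsIOError(f"results at {path} lack table {name!r}")
            df = pd.read_csv(StringIO(files[csv_name]))
            if name in _TABLE_KEYS:
                bundle[name] = df
            else:
                recorded[name] = df
        if recorded:
            bundle["recorded_variables"] = recorded
        bundles.append(bundle)
    return bundles[0] if len(bundles) == 1 else bundles


# ------------------------------------------------------------------- frames


@dataclass
class ExtractedFrames:
    """Task-level summary frames pooled over a batch of simulations."""

    firing_rates: pd.DataFrame
    rt_dist: pd.DataFrame
    reward_q: pd.DataFrame | None = None
    performance: pd.DataFrame | None = None
    total_performance: float | None = None


def extract_frames(
    results: ResultsBundle | Sequence[ResultsBundle],
    task: str | None = None,
) -> ExtractedFrames:
    """Pool behavioral/neural frames across simulations.

    ``performance`` is the percentage of decided trials selecting each
    action; ``total_performance`` the percentage of decided trials whose
    decision matched the optimal action; ``rt_dist`` the decision times of
    decided trials.  A batch with no decided trials reports NaN rather than
    failing.  For the stop-signal task only firing rates and the reaction
    time distribution are returned.
    """
    bundles = [results] if isinstance(results, dict) else list(results)
    if not bundles:
        raise ConfigError("extract_frames needs at least one results bundle")
    if task is None:
        task = bundles[0].get("experimentchoice", "n-choice")

    fr_parts = []
    dt_parts = []
    for i, b in enumerate(bundles):
        fr = b["popfreqs"].melt(id_vars=["Time"], var_name="population", value_name="rate")
        fr["sim"] = i
        fr_parts.append(fr)
        dt = b["datatables"].copy()
        dt["sim"] = i
        dt_parts.append(dt)
    firing_rates = pd.concat(fr_parts, ignore_index=True)
    datatables = pd.concat(dt_parts, ignore_index=True)

    decided = datatables[datatables["decision"] != "none"]
    rt_dist = decided[["sim", "trial", "decisiontime"]].reset_index(drop=True)
    if task == "stop-signal":
        return ExtractedFrames(firing_rates=firing_rates, rt_dist=rt_dist)

    channels = list(bundles[0]["Q_df"].columns)
    if len(decided):
        counts = decided["decision"].value_counts()
        perf = pd.DataFrame(
            {
                "action": channels,
                "percentage": [100.0 * counts.get(ch, 0) / len(decided) for ch in channels],
            }
        )
        total = 100.0 * float(
            (decided["decision"] == decided["correctdecision"]).mean()
        )
    else:  # no decided trials: undefined, not a division error
        perf = pd.DataFrame({"action": channels, "percentage": [float("nan")] * len(channels)})
        total = float("nan")

    rq_parts = []
    for i, b in enumerate(bundles):
        q = b["Q_df"].copy()
        q.columns = [f"Q_{c}" for c in q.columns]
        q["trial"] = np.arange(len(q)) - 1  # row 0 is the initial value
        q["sim"] = i
        rew = b["datatables"][["trial", "reward", "decision"]]
        rq = q.merge(rew, on="trial", how="left")
        rq_parts.append(rq)
    reward_q = pd.concat(rq_parts, ignore_index=True)

    return ExtractedFrames(
        firing_rates=firing_rates,
        rt_dist=rt_dist,
        reward_q=reward_q,
        performance=perf,
        total_performance=total,
    )
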