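"""Run-directory output, provenance manifests and comparison reports.

All outputs are plain TSV/JSON so downstream analysis is language-agnostic:

- ``summary.tsv`` — per-reaction percentile summary of the Pro control
  coefficient (the headline table of a run);
- ``full_summary.tsv`` — the same for every internal metabolite;
- ``correlations.tsv`` — Pearson correlation matrix of per-run Pro control
  coefficients across reaction pairs;
- ``runs.tsv`` — the per-run Pro control coefficients (one row per run);
- ``config.json`` / ``manifest.json`` — configuration echo and provenance
  (tool version, seed, input checksums, discard counts, timestamp).

``compare_with_reference`` renders a side-by-side table of a computed
summary against the bundled previously published estimates, flagging each
row as passing when the computed value lies within a relative tolerance of
the reference median or inside the reference (P10, P90) interval, with
matching sign.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .ensemble import EnsembleResult

__all__ = [
    "write_run_outputs",
    "load_run_summary",
    "load_reference_summaries",
    "load_reference_correlations",
    "compare_with_reference",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _config_dict(result: EnsembleResult) -> dict:
    cfg = dataclasses.asdict(result.config)
    cfg["boundary"] = dataclasses.asdict(result.config.boundary)
    return cfg


def write_run_outputs(
    result: EnsembleResult,
    outdir: str | Path,
    input_paths: dict[str, str | Path] | None = None,
) -> Path:
    """Write the full output bundle for one ensemble run; returns the directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    result.summarize("Pro").to_csv(outdir / "summary.tsv", sep="\t", index=False)

    frames = []
    for met in result.metabolites:
        df = result.summarize(met)
        df.insert(0, "metabolite", met)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "full_summary.tsv", sep="\t", index=False
    )

    result.correlate("Pro").to_csv(outdir / "correlations.tsv", sep="\t")

    runs = pd.DataFrame(result.metabolite_control("Pro"), columns=result.reactions)
    runs.insert(0, "run", np.arange(len(runs)))
    runs.to_csv(outdir / "runs.tsv", sep="\t", index=False)

    with open(outdir / "config.json", "w") as fh:
        json.dump(_config_dict(result), fh, indent=1)
        fh.write("\n")

    manifest = {
        "tool": "mcmca",
        "version": _version,
        "condition": result.condition,
        "seed": result.config.seed,
        "n_runs": result.config.n_runs,
        "discarded_singular_draws": result.discarded,
        "flux_rejections": result.flux_rejections,
        "max_theorem_deviation": result.theorem_deviation,
        "config": _config_dict(result),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (input_paths or {}).items()
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return outdir


def load_run_summary(rundir: str | Path) -> pd.DataFrame:
    rundir = Path(rundir)
    path = rundir / "summary.tsv"
    if not path.exists():
        raise FileNotFoundError(f"{rundir} is not a completed run directory (no summary.tsv)")
    return pd.read_csv(path, sep="\t")


def _data_file(name: str) -> Path:
    from . import data_path

    return Path(str(data_path(name)))


def load_reference_summaries(condition: str) -> pd.DataFrame:
    """Bundled previously published percentile summaries for ``lp`` or ``ml``."""
    df = pd.read_csv(_data_file("reference_control_summaries.tsv"), sep="\t", comment="#")
    sel = df[df["condition"] == condition.lower()].drop(columns="condition")
    if sel.empty:
        raise ValueError(f"no bundled reference summaries for condition {condition!r}")
    return sel.reset_index(drop=True)


def load_reference_correlations(condition: str) -> pd.DataFrame:
    """Bundled previously published correlation coefficients for ``lp`` or ``ml``."""
    df = pd.read_csv(_data_file("reference_correlations.tsv"), sep="\t", comment="#")
    sel = df[df["condition"] == condition.lower()].drop(columns="condition")
    if sel.empty:
        raise ValueError(f"no bundled reference correlations for condition {condition!r}")
    return sel.reset_index(drop=True)


def compare_with_reference(
    summary: pd.DataFrame, condition: str, tolerance: float = 0.5
) -> pd.DataFrame:
    """Side-by-side comparison of a computed summary with the published one.

    A row passes when signs of the medians agree and the computed median is
    either within ``tolerance`` relative deviation of the reference median or
    inside the reference (P10, P90) interval.
    """
    ref = load_reference_summaries(condition).set_index("reaction")
    comp = summary.set_index("reaction")
    rows = []
    for rid in ref.index:
        if rid not in comp.index:
            continue
        c_med = float(comp.loc[rid, "median"])
        r_med = float(ref.loc[rid, "median"])
        r10, r90 = float(ref.loc[rid, "p10"]), float(ref.loc[rid, "p90"])
        rel = abs(c_med - r_med) / abs(r_med) if r_med != 0 else np.inf
        in_band = min(r10, r90) <= c_med <= max(r10, r90)
        sign_ok = np.sign(c_med) == np.sign(r_med) or in_band
        rows.append(
            {
                "reaction": rid,
                "median": c_med,
                "p10": float(comp.loc[rid, "p10"]),
                "p90": float(comp.loc[rid, "p90"]),
                "ref_median": r_med,
                "ref_p10": r10,
                "ref_p90": r90,
                "rel_deviation": rel,
                "within_ref_band": in_band,
                "passed": bool(sign_ok and (rel <= tolerance or in_band)),
            }
        )
    return pd.DataFrame(rows)
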