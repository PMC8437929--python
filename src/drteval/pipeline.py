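"""Study orchestration: phantom -> tracking -> selection -> metrics -> report.

A run evaluates the three study arms over one phantom "subject":

* **congruence** — agreement between tract renditions of different methods
  (the internal deterministic tracker plus any externally supplied
  tractograms), per variant, as z-resolved COG distance and Dice;
* **retest** — reproducibility between two repeat sessions of the same
  acquisition (independent noise realisations) for the internal tracker;
* **validity** — placement of the per-level density COG against the
  reference nucleus masks (Vim, RN, SCP).

A variant whose selection retains zero streamlines is a first-class result
("reconstruction failed"), not an error.  All randomness derives from the
configured seed, and re-running a config reproduces every CSV byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .density_metrics import (CongruenceResult, DensityMap, MetricParams,
                              ValidityResult, congruence_profile,
                              render_density, validity_cog, warp_density)
from .io_formats import DWIVolume, MaskSet, Tractogram, read_tractogram
from .selection import SelectionSpec, resolve_sides, select_drt
from .synthetic_data import (GroundTruth, PhantomSpec, WarpField,
                             make_phantom, make_session_pair)
from .tensor_model import fit_tensor_lls
from .tracking import TrackingParams, track

__all__ = ["RunConfig", "load_config", "run_study", "summarize", "StudyReport"]

INTERNAL_METHOD = "fact"


@dataclass
class RunConfig:
    """Fully resolved configuration of a study run."""

    seed: int = 0
    out_dir: str = "drteval_out"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    metrics: MetricParams = field(default_factory=MetricParams)
    dn_side: str = "L"
    variants: Sequence[str] = ("uncrossed", "crossed")
    laterality: str = "drtx_crosses"
    retest: bool = True
    self_comparison: bool = True
    validity: bool = True
    external_tractograms: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # the study seed drives every stochastic stage
        self.phantom = (self.phantom if isinstance(self.phantom, PhantomSpec)
                        else PhantomSpec(**self.phantom))
        if not isinstance(self.tracking, TrackingParams):
            self.tracking = TrackingParams(**self.tracking)
        if not isinstance(self.metrics, MetricParams):
            self.metrics = MetricParams(**self.metrics)
        object.__setattr__(self.phantom, "seed", int(self.seed))


def load_config(path) -> RunConfig:
    """Read a YAML run configuration; missing keys take their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


@dataclass
class StudyReport:
    """In-memory report bundle returned by :func:`run_study`."""

    congruence: pd.DataFrame
    retest: pd.DataFrame
    validity: pd.DataFrame
    summary: Dict[str, dict]
    log: List[dict]
    selected_counts: Dict[Tuple[str, int, str], int]


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _profile_rows(kind: str, label_a: str, label_b: str, variant: str,
                  result: Optional[CongruenceResult]) -> pd.DataFrame:
    if result is None:
        return pd.DataFrame([{
            "kind": kind, "a": label_a, "b": label_b, "variant": variant,
            "z_mm": np.nan, "cog_distance_mm": np.nan, "dice": np.nan,
            "defined": False, "status": "reconstruction failed",
        }])
    df = result.to_dataframe()
    df.insert(0, "kind", kind)
    df.insert(1, "a", label_a)
    df.insert(2, "b", label_b)
    df.insert(3, "variant", variant)
    df["status"] = "ok"
    return df


def _summary_entry(result: Optional[CongruenceResult],
                   params: MetricParams) -> dict:
    if result is None:
        return {"status": "reconstruction failed"}
    entry = {"status": "ok", **result.aggregate()}
    for name, z in params.eval_levels.items():
        entry[name] = result.at_level(z)
    return entry


def _warp_mask(mask: np.ndarray, native_affine: np.ndarray,
               warp: WarpField) -> np.ndarray:
    dm = DensityMap(data=np.asarray(mask, float), affine=native_affine,
                    space_tag="native")
    return warp_density(dm, warp).data >= 0.5


def run_study(config: RunConfig, write: bool = True) -> StudyReport:
    """Execute the configured study arms and (optionally) write the report.

    Outputs under ``config.out_dir``: ``congruence.csv``, ``retest.csv``,
    ``validity.csv`` (one row per z-level / eval level), ``summary.json``
    (aggregates) and ``run.log`` (JSON-lines provenance: parameters, seeds
    and input digests).
    """
    log: List[dict] = []
    params = config.metrics

    # --- inputs -----------------------------------------------------------
    if config.retest and not math.isinf(config.phantom.snr):
        s1, s2, gt = make_session_pair(config.phantom)
        sessions = [s1, s2]
    else:
        dwi, gt = make_phantom(config.phantom)
        sessions = [dwi, dwi] if config.retest else [dwi]
    log.append({"stage": "phantom", "spec": asdict(config.phantom),
                "sessions": len(sessions),
                "digests": [_digest(s.data) for s in sessions]})

    # --- per-session tracking --------------------------------------------
    tractograms: Dict[str, List[Tractogram]] = {}
    internal = []
    for i, dwi in enumerate(sessions):
        field_ = fit_tensor_lls(dwi)
        tg = track(field_, gt.masks["WM"], config.tracking)
        internal.append(tg)
        log.append({"stage": "track", "session": i, "method": INTERNAL_METHOD,
                    "n_streamlines": len(tg)})
    tractograms[INTERNAL_METHOD] = internal
    for name, path in config.external_tractograms.items():
        tg = read_tractogram(path)
        tractograms[name] = [tg] * len(sessions)
        log.append({"stage": "ingest", "method": name, "path": str(path),
                    "n_streamlines": len(tg)})

    # --- selection + density per (method, session, variant) ---------------
    densities: Dict[Tuple[str, int, str], Optional[DensityMap]] = {}
    counts: Dict[Tuple[str, int, str], int] = {}
    for method, tgs in tractograms.items():
        for i, tg in enumerate(tgs):
            for variant in config.variants:
                spec = SelectionSpec(variant=variant, dn_side=config.dn_side,
                                     laterality=config.laterality)
                sel = select_drt(tg, gt.masks, spec)
                counts[(method, i, variant)] = len(sel)
                log.append({"stage": "select", "method": method, "session": i,
                            "variant": variant, "n_selected": len(sel)})
                if len(sel) == 0:
                    densities[(method, i, variant)] = None
                    continue
                native = render_density(sel, gt.masks.shape, gt.affine)
                densities[(method, i, variant)] = warp_density(native, gt.warp)

    # --- comparisons -------------------------------------------------------
    cong_rows, retest_rows, val_rows = [], [], []
    summary: Dict[str, dict] = {"congruence": {}, "retest": {}, "validity": {}}

    methods = list(tractograms)
    pairs = list(combinations(methods, 2))
    if config.self_comparison:
        pairs = [(m, m) for m in methods] + pairs
    for a, b in pairs:
        for variant in config.variants:
            da, db = densities.get((a, 0, variant)), densities.get((b, 0, variant))
            res = (congruence_profile(da, db, params, label=f"{a}|{b}")
                   if da is not None and db is not None else None)
            cong_rows.append(_profile_rows("congruence", a, b, variant, res))
            summary["congruence"][f"{a}|{b}|{variant}"] = _summary_entry(res, params)

    if config.retest and len(sessions) == 2:
        for variant in config.variants:
            da = densities.get((INTERNAL_METHOD, 0, variant))
            db = densities.get((INTERNAL_METHOD, 1, variant))
            res = (congruence_profile(da, db, params, label="retest")
                   if da is not None and db is not None else None)
            retest_rows.append(_profile_rows("retest", f"{INTERNAL_METHOD}/s1",
                                             f"{INTERNAL_METHOD}/s2", variant, res))
            summary["retest"][f"{INTERNAL_METHOD}|{variant}"] = \
                _summary_entry(res, params)

    if config.validity:
        for method in methods:
            for variant in config.variants:
                dm = densities.get((method, 0, variant))
                key = f"{method}|{variant}"
                if dm is None:
                    summary["validity"][key] = {"status": "reconstruction failed"}
                    continue
                sides = resolve_sides(SelectionSpec(
                    variant=variant, dn_side=config.dn_side,
                    laterality=config.laterality))
                target = sides["PG"]
                refs = {
                    "vim": _warp_mask(gt.masks[f"VIM_{target}"], gt.affine, gt.warp),
                    "rn_stn": _warp_mask(gt.masks[f"RN_{target}"], gt.affine, gt.warp),
                    "scp": _warp_mask(gt.masks[f"SCP_{target}"], gt.affine, gt.warp),
                }
                vres = validity_cog(dm, params, refs, label=key)
                df = vres.to_dataframe()
                df.insert(0, "method", method)
                df.insert(1, "variant", variant)
                val_rows.append(df)
                summary["validity"][key] = {"status": "ok", **vres.levels}

    summary["selected_counts"] = {
        f"{m}|s{i}|{v}": n for (m, i, v), n in counts.items()}

    report = StudyReport(
        congruence=pd.concat(cong_rows, ignore_index=True) if cong_rows
        else pd.DataFrame(),
        retest=pd.concat(retest_rows, ignore_index=True) if retest_rows
        else pd.DataFrame(),
        validity=pd.concat(val_rows, ignore_index=True) if val_rows
        else pd.DataFrame(),
        summary=summary, log=log, selected_counts=counts,
    )
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.congruence.to_csv(out / "congruence.csv", index=False)
        report.retest.to_csv(out / "retest.csv", index=False)
        report.validity.to_csv(out / "validity.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        with open(out / "run.log", "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry, default=str) + "\n")
    return report


def summarize(report: StudyReport, params: Optional[MetricParams] = None
              ) -> pd.DataFrame:
    """One summary row per comparison: z-aggregates plus the eval levels."""
    params = params or MetricParams()
    rows = []
    for kind in ("congruence", "retest"):
        for key, entry in report.summary[kind].items():
            row = {"kind": kind, "comparison": key,
                   "status": entry.get("status", "ok")}
            if entry.get("status") == "ok":
                row.update({k: entry[k] for k in
                            ("cog_mean_mm", "cog_median_mm",
                             "dice_mean", "dice_median")})
                for name in params.eval_levels:
                    lvl = entry.get(name, {})
                    row[f"cog_{name}_mm"] = lvl.get("cog_distance_mm")
                    row[f"dice_{name}"] = lvl.get("dice")
            rows.append(row)
    return pd.DataFrame(rows)
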