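"""Study orchestration: from trajectory files to condition-level tables.

A *study* is a set of sessions, each holding one dyad (a small and a large
subject) recorded under one condition (control / match / mismatch), with
optional replica trajectories for the teleported conditions.  For every
condition the pipeline produces:

* transfer entropy in both directions and net transfer entropy, each with
  surrogate quantiles and permutation p-values (one table row per
  condition);
* speed and turn-rate cross-correlation maxima and signed lags with their
  tests (leader-follower table);
* per-session replica-similarity summaries where replicas exist.

The tested statistic is always the across-pair average, and each surrogate
replicate re-averages per-pair surrogates, so a condition yields one number
and one p-value per statistic.  Failures are quarantined per session and
reported, never silently dropped.  Everything is deterministic given
(inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .infotheory import te_from_segments
from .kinematics import Condition, compute_kinematics, fill_gaps
from .surrogates import permutation_test
from .symbolize import SymbolSeries, symbolize
from .synthetic import ChannelConfig, DyadSimConfig, simulate_dyad, teleport_channel
from .xcorr import leader_follower_summary, similarity_index

__all__ = ["SessionSpec", "StudyConfig", "run_study", "make_study_fixture", "load_study_config"]

log = logging.getLogger("dyadkit")


@dataclass
class SessionSpec:
    """File references for one dyad session."""

    pair_id: str
    condition: Condition
    small_path: str
    large_path: str
    small_replica_path: str | None = None
    large_replica_path: str | None = None

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)


@dataclass
class StudyConfig:
    """Sessions plus the analysis parameters applied to all of them."""

    sessions: list[SessionSpec]
    k: int = 1
    log_base: float = 2.0
    n_surrogates: int = 20_000
    surrogate_method: str = "rotate"
    smooth_window: float = 0.1     # seconds
    max_gap: float = 0.5           # seconds
    max_lag: float = 1.0           # seconds, lag-scan half-width
    similarity_window: float = 20.0  # seconds
    seed: int = 0
    output_dir: str = "study_output"

    def __post_init__(self) -> None:
        if not self.sessions:
            raise ValueError("no sessions")
        seen = set()
        for s in self.sessions:
            key = (s.pair_id, s.condition)
            if key in seen:
                raise ValueError(f"duplicate session {key}")
            seen.add(key)


def load_study_config(path: str | Path) -> StudyConfig:
    """Load a StudyConfig from a YAML file (paths relative to the file)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    root = path.parent

    def _abs(p):
        return str((root / p).resolve()) if p else None

    sessions = [
        SessionSpec(
            pair_id=s["pair_id"],
            condition=s["condition"],
            small_path=_abs(s["small"]),
            large_path=_abs(s["large"]),
            small_replica_path=_abs(s.get("small_replica")),
            large_replica_path=_abs(s.get("large_replica")),
        )
        for s in raw["sessions"]
    ]
    params = {k: v for k, v in raw.items() if k != "sessions"}
    return StudyConfig(sessions=sessions, **params)


# ---------------------------------------------------------------- statistics

def _mean_te(pairs: list[tuple[SymbolSeries, SymbolSeries]], k: int, base: float) -> float:
    vals = [
        te_from_segments(src.segments(), dst.segments(), k=k, base=base)[0]
        for src, dst in pairs
    ]
    return float(np.mean(vals))


def _mean_net_te(pairs: list[tuple[SymbolSeries, SymbolSeries]], k: int, base: float) -> float:
    vals = []
    for small, large in pairs:
        s2l = te_from_segments(small.segments(), large.segments(), k=k, base=base)[0]
        l2s = te_from_segments(large.segments(), small.segments(), k=k, base=base)[0]
        vals.append(s2l - l2s)
    return float(np.mean(vals))


# ---------------------------------------------------------------- main entry

def _prepare_session(spec: SessionSpec, cfg: StudyConfig) -> dict:
    out: dict = {"spec": spec}
    small = fill_gaps(dio.read_trajectory(spec.small_path), max_gap=cfg.max_gap)
    large = fill_gaps(dio.read_trajectory(spec.large_path), max_gap=cfg.max_gap)
    out["small_traj"], out["large_traj"] = small, large
    ks = compute_kinematics(small, smooth_window=cfg.smooth_window)
    kl = compute_kinematics(large, smooth_window=cfg.smooth_window)
    out["small_kin"], out["large_kin"] = ks, kl
    out["small_sym"] = symbolize(ks)
    out["large_sym"] = symbolize(kl)
    for role, path in (("small", spec.small_replica_path), ("large", spec.large_replica_path)):
        if path:
            fish = out[f"{role}_traj"]
            replica = dio.read_trajectory(path)
            out[f"{role}_similarity"] = similarity_index(
                fish, replica, window=cfg.similarity_window, max_lag=cfg.max_lag
            )
    return out


def _condition_tests(sessions: list[dict], cfg: StudyConfig, rng: np.random.Generator) -> dict:
    sym_pairs = [(s["small_sym"], s["large_sym"]) for s in sessions]
    kin_pairs = [(s["small_kin"], s["large_kin"]) for s in sessions]
    k, base, nsur, meth = cfg.k, cfg.log_base, cfg.n_surrogates, cfg.surrogate_method

    res: dict = {}
    res["te_small_to_large"] = permutation_test(
        lambda ps: _mean_te(ps, k, base), sym_pairs,
        n_surrogates=nsur, tail="one_tailed_upper", rng=rng, method=meth,
    ).to_record()
    res["te_large_to_small"] = permutation_test(
        lambda ps: _mean_te([(b, a) for a, b in ps], k, base), sym_pairs,
        n_surrogates=nsur, tail="one_tailed_upper", rng=rng, method=meth,
    ).to_record()
    res["net_te"] = permutation_test(
        lambda ps: _mean_net_te(ps, k, base), sym_pairs,
        n_surrogates=nsur, tail="two_tailed", rng=rng, method=meth,
    ).to_record()
    for channel in ("speed", "turn_rate"):
        corr_t, lag_t = leader_follower_summary(
            kin_pairs, channel=channel, max_lag=cfg.max_lag,
            n_surrogates=nsur, rng=rng, method=meth,
        )
        res[f"xcorr_{channel}"] = corr_t.to_record()
        res[f"lag_{channel}"] = lag_t.to_record()
    return res


def run_study(cfg: StudyConfig) -> dict:
    """Run the full analysis and write JSON + CSV tables to the output dir.

    Returns the report dict.  Per-session failures are quarantined with
    their error message; conditions are analyzed over the surviving
    sessions.
    """
    t0 = time.time()
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    prepared: dict[Condition, list[dict]] = {}
    quarantined: list[dict] = []
    for spec in cfg.sessions:
        t1 = time.time()
        try:
            sess = _prepare_session(spec, cfg)
            prepared.setdefault(spec.condition, []).append(sess)
            log.info(
                "session=%s condition=%s stage=prepare ok elapsed=%.2fs",
                spec.pair_id, spec.condition.value, time.time() - t1,
            )
        except Exception as exc:  # quarantine, never drop silently
            quarantined.append(
                {"pair_id": spec.pair_id, "condition": spec.condition.value, "error": str(exc)}
            )
            log.warning(
                "session=%s condition=%s stage=prepare FAILED: %s",
                spec.pair_id, spec.condition.value, exc,
            )

    report: dict = {
        "parameters": {
            "k": cfg.k, "log_base": cfg.log_base, "n_surrogates": cfg.n_surrogates,
            "surrogate_method": cfg.surrogate_method, "smooth_window_s": cfg.smooth_window,
            "max_lag_s": cfg.max_lag, "similarity_window_s": cfg.similarity_window,
            "seed": cfg.seed,
        },
        "n_sessions_configured": len(cfg.sessions),
        "n_sessions_analyzed": sum(len(v) for v in prepared.values()),
        "quarantined": quarantined,
        "conditions": {},
        "similarity": [],
    }
    for cond, sessions in prepared.items():
        t1 = time.time()
        report["conditions"][cond.value] = _condition_tests(sessions, cfg, rng)
        report["conditions"][cond.value]["n_pairs"] = len(sessions)
        log.info("condition=%s stage=tests ok elapsed=%.2fs", cond.value, time.time() - t1)
        for sess in sessions:
            for role in ("small", "large"):
                sim = sess.get(f"{role}_similarity")
                if sim is not None:
                    rec = sim.to_record()
                    rec.update(
                        pair_id=sess["spec"].pair_id,
                        condition=cond.value,
                        subject=role,
                    )
                    report["similarity"].append(rec)

    _write_tables(report, outdir)
    (outdir / "study_report.json").write_text(json.dumps(report, indent=2))
    log.info("study complete: %d conditions, %.1fs", len(prepared), time.time() - t0)
    return report


def _write_tables(report: dict, outdir: Path) -> None:
    """Flat CSV tables: one row per condition, columns = stat/quantiles/p."""
    te_rows, xc_rows = [], []
    for cond, res in report["conditions"].items():
        row = {"condition": cond}
        for key in ("te_small_to_large", "te_large_to_small", "net_te"):
            r = res[key]
            row[f"{key}"] = r["observed"]
            row[f"{key}_q95"] = r["quantile_95"]
            row[f"{key}_q2.5"] = r["quantile_2_5"]
            row[f"{key}_q97.5"] = r["quantile_97_5"]
            row[f"{key}_p"] = r["p_value"]
        te_rows.append(row)
        row = {"condition": cond}
        for channel in ("speed", "turn_rate"):
            for key in (f"xcorr_{channel}", f"lag_{channel}"):
                r = res[key]
                row[key] = r["observed"]
                row[f"{key}_q95"] = r["quantile_95"]
                row[f"{key}_q2.5"] = r["quantile_2_5"]
                row[f"{key}_q97.5"] = r["quantile_97_5"]
                row[f"{key}_p"] = r["p_value"]
        xc_rows.append(row)
    pd.DataFrame(te_rows).to_csv(outdir / "transfer_entropy.csv", index=False)
    pd.DataFrame(xc_rows).to_csv(outdir / "cross_correlation.csv", index=False)
    if report["similarity"]:
        pd.DataFrame(report["similarity"]).to_csv(outdir / "similarity.csv", index=False)


# ---------------------------------------------------------------- fixtures

def make_study_fixture(
    outdir: str | Path,
    n_pairs: int = 12,
    duration: float = 600.0,
    frame_rate: float = 30.0,
    coupling_strength: float = 0.6,
    coupling_lag: float = 0.1,
    seed: int = 0,
    channel: ChannelConfig | None = None,
) -> Path:
    """Materialize a synthetic 3-condition study on disk; returns the config path.

    Mirrors the study design the pipeline targets: ``n_pairs`` dyads kept
    identical across three conditions.  Control dyads are coupled with a
    small leader; match dyads add a relay channel producing replicas;
    mismatch dyads are generated uncoupled (no asymmetric interaction to
    recover).  Per-condition seeds derive from ``seed`` so the whole study
    is reproducible.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    channel = channel or ChannelConfig(delay=0.1, position_noise_sd=0.2)
    sessions = []
    for i in range(n_pairs):
        for j, cond in enumerate(Condition):
            coupled = cond is not Condition.MISMATCH
            cfg = DyadSimConfig(
                duration=duration, frame_rate=frame_rate,
                coupling_strength=coupling_strength if coupled else 0.0,
                attraction_gain=0.8 if coupled else 0.0,
                coupling_lag=coupling_lag,
                condition=cond, pair_id=f"pair{i:02d}",
                seed=seed * 1000 + i * 10 + j,
            )
            small, large = simulate_dyad(cfg)
            entry = {"pair_id": cfg.pair_id, "condition": cond.value}
            for role, traj in (("small", small), ("large", large)):
                rel = f"{cfg.pair_id}_{cond.value}_{role}.csv"
                dio.write_trajectory(traj, outdir / rel)
                entry[role] = rel
                if cond is not Condition.CONTROL:
                    replica = teleport_channel(
                        traj, channel, rng=np.random.default_rng(cfg.seed + 7)
                    )
                    rel_r = f"{cfg.pair_id}_{cond.value}_{role}_replica.csv"
                    dio.write_trajectory(replica, outdir / rel_r)
                    entry[f"{role}_replica"] = rel_r
            sessions.append(entry)
    config = {
        "sessions": sessions,
        "seed": seed,
        "output_dir": str(outdir / "results"),
    }
    cfg_path = outdir / "study.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return cfg_path
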