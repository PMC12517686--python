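"""End-to-end orchestration: preprocess -> behavior -> synchrony ->
correlograms -> LFP -> subVm -> spatial, with CSV exports, a deterministic
JSON summary, and ground-truth scoring for synthetic sessions.

All stage randomness derives from one master seed through a fixed
SeedSequence spawn order (jitter surrogates, pairwise CCGs, LFP shuffles,
subVm shuffles, spatial permutations), so reruns with the same seed are
byte-identical.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import behavior as beh
from . import correlograms as ccg
from . import lfp as lfpmod
from . import preprocess as prep
from . import spatial as spa
from . import subvm as sub
from . import synchrony as syn
from .session import SessionBundle
from .simulate import GroundTruth

STAGES = ("preprocess", "behavior", "synchrony", "correlograms",
          "lfp", "subvm", "spatial")


@dataclass
class RunConfig:
    """Pipeline parameters; defaults reproduce the reference analysis."""
    master_seed: int = 0
    out_dir: str | None = None
    stages: tuple = STAGES
    window_ms: float = 25.0
    jitter_halfwidth_ms: float = 75.0
    n_jitters_sync: int = 500
    n_jitters_pairwise: int = 1000
    k_sd: float = 4.0
    ccg_window_ms: float = 500.0
    min_pair_counts: int = 100
    ripple_band_hz: tuple = (120.0, 240.0)
    ripple_upper_sd: float = 7.0
    ripple_lower_sd: float = 3.5
    ripple_min_duration_ms: float = 30.0
    theta_band_hz: tuple = (4.0, 12.0)
    n_shuffles_modulation: int = 1000
    n_bins_spatial: int = 36
    n_permutations_spatial: int = 10000
    triggered_lfp_halfwidth_s: float = 1.0
    subvm_halfwidth_s: float = 0.3


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_rngs(master_seed: int) -> dict:
    children = np.random.SeedSequence(master_seed).spawn(5)
    names = ("sync_jitter", "pairwise_ccg", "lfp_shuffles", "subvm_shuffles",
             "spatial_perm")
    return {name: np.random.default_rng(s) for name, s in zip(names, children)}


def _jsonable(x):
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return None if not np.isfinite(v) else v
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_pipeline(bundle: SessionBundle, run_config: RunConfig | None = None):
    """Execute the analysis stages on one session; returns the report dict.

    When ``run_config.out_dir`` is set the CSV exports, summary JSON and run
    log are written there.
    """
    rc = run_config or RunConfig()
    rngs = _stage_rngs(rc.master_seed)
    fs = bundle.imaging_rate_hz
    duration = bundle.duration_s
    report: dict = {"session_id": bundle.session_id, "master_seed": rc.master_seed,
                    "version": __version__}
    tables: dict[str, pd.DataFrame] = {}
    activities: list[prep.CellActivity] = []
    included: set = set()
    spike_trains: dict[str, np.ndarray] = {}
    states = None
    events = None
    centroids = {c.cell_id: np.asarray(c.centroid_xy) for c in bundle.cells}

    def stage_on(name):
        return name in rc.stages

    # --- preprocess ---------------------------------------------------
    if stage_on("preprocess"):
        try:
            for c in bundle.cells:
                activities.append(prep.process_cell(c.cell_id, c.raw_f,
                                                    fs, duration))
            included, analyzable = prep.qc_cells(activities, centroids, duration)
            spike_trains = {a.cell_id: a.spike_times for a in activities
                            if a.cell_id in included}
            tables["qc_report"] = prep.qc_report(activities, centroids)
            tables["spikes"] = prep.spike_table(
                [a for a in activities if a.cell_id in included])
            report["preprocess"] = {
                "n_cells": len(activities),
                "n_included": len(included),
                "session_analyzable": bool(analyzable),
                "median_rate_hz": float(np.median(
                    [a.mean_rate_hz for a in activities if a.cell_id in included]))
                if included else None,
                "median_snr": float(np.median(
                    [a.snr for a in activities if a.cell_id in included]))
                if included else None,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("preprocess", e) from e

    # --- behavior -----------------------------------------------------
    if stage_on("behavior"):
        try:
            states = beh.classify_states(bundle.behavior.speed_cm_s, fs)
            tables["state_intervals"] = states.to_frame()
            rows = []
            for a in activities:
                if a.cell_id not in included:
                    continue
                r_loco, r_immo = beh.state_rates(a.spike_times, states)
                try:
                    r = beh.rate_speed_correlation(a.spike_times,
                                                   bundle.behavior.speed_cm_s, fs)
                except ValueError:
                    r = np.nan
                rows.append({"cell_id": a.cell_id, "rate_loco_hz": r_loco,
                             "rate_immo_hz": r_immo, "rate_speed_r": r})
            tables["state_rates"] = pd.DataFrame(rows)
            report["behavior"] = {
                "loco_fraction": states.duration("locomotion") / duration,
                "immo_fraction": states.duration("immobility") / duration,
                "median_rate_speed_r": float(np.nanmedian(
                    [r["rate_speed_r"] for r in rows])) if rows else None,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("behavior", e) from e

    # --- synchrony ----------------------------------------------------
    if stage_on("synchrony") and spike_trains:
        try:
            events = syn.detect_population_synchrony(
                spike_trains, duration, fs, rc.window_ms,
                rc.jitter_halfwidth_ms, rc.n_jitters_sync, rc.k_sd,
                seed=rngs["sync_jitter"])
            tables["sync_events"] = events.to_frame()
            rates = syn.event_rate_segments(events, duration, 2)
            report["synchrony"] = {
                "n_events": events.n_events,
                "event_rate_hz": events.n_events / duration,
                "segment_rates_hz": rates.tolist(),
                "median_ensemble_size_pct": float(np.median(events.ensemble_size_pct))
                if events.n_events else None,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("synchrony", e) from e

    # --- correlograms ---------------------------------------------------
    pair_results = {}
    if stage_on("correlograms") and spike_trains:
        try:
            ids = sorted(spike_trains)
            grand_rows = []
            for cid in ids:
                others = [spike_trains[o] for o in ids if o != cid]
                try:
                    g = ccg.grand_average_ccg(spike_trains[cid], others,
                                              rc.ccg_window_ms)
                    grand_rows.append({"cell_id": cid, "peak_lag_ms": g.peak_lag_ms,
                                       "fwhm_ms": g.fwhm_ms})
                except (ccg.UndefinedCcgError, ValueError):
                    continue
            tables["grand_ccg"] = pd.DataFrame(grand_rows)
            state_sets = {"all": None}
            if states is not None:
                state_sets["immobility"] = states.immobility
                state_sets["locomotion"] = states.locomotion
            rows = []
            for a_id, b_id in itertools.combinations(ids, 2):
                for state, ivs in state_sets.items():
                    try:
                        r = ccg.pairwise_ccg(
                            spike_trains[a_id], spike_trains[b_id], duration,
                            state_intervals=ivs, state=state,
                            n_jitters=rc.n_jitters_pairwise,
                            jitter_halfwidth_ms=rc.jitter_halfwidth_ms,
                            seed=rngs["pairwise_ccg"],
                            window_ms=rc.ccg_window_ms,
                            min_counts=rc.min_pair_counts)
                        pair_results[(a_id, b_id, state)] = r
                        rows.append({"cell_a": a_id, "cell_b": b_id, "state": state,
                                     "peak_lag_ms": r.peak_lag_ms, "fwhm_ms": r.fwhm_ms,
                                     "sync_strength": r.sync_strength,
                                     "p_value": r.p_value,
                                     "n_counts": r.n_pair_counts,
                                     "excluded_reason": ""})
                    except ccg.PairExcludedError as exc:
                        rows.append({"cell_a": a_id, "cell_b": b_id, "state": state,
                                     "peak_lag_ms": np.nan, "fwhm_ms": np.nan,
                                     "sync_strength": np.nan, "p_value": np.nan,
                                     "n_counts": 0, "excluded_reason": exc.reason})
            tables["pairwise_ccg"] = pd.DataFrame(rows)
            fwhms = [r["fwhm_ms"] for r in grand_rows if np.isfinite(r["fwhm_ms"])]
            report["correlograms"] = {
                "median_grand_fwhm_ms": float(np.median(fwhms)) if fwhms else None,
                "n_pairs_analyzed": len(pair_results),
                "pct_significant_pairs": 100.0 * float(np.mean(
                    [r.p_value < 0.05 for k, r in pair_results.items()
                     if k[2] == "all"])) if pair_results else None,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("correlograms", e) from e

    # --- lfp ------------------------------------------------------------
    if stage_on("lfp"):
        try:
            lfp_fs = bundle.lfp.sampling_rate_hz
            ripples = lfpmod.detect_ripples(
                bundle.lfp.samples, lfp_fs, rc.ripple_band_hz,
                upper_sd=rc.ripple_upper_sd, lower_sd=rc.ripple_lower_sd,
                min_duration_ms=rc.ripple_min_duration_ms)
            tables["ripples"] = pd.DataFrame(
                [{"start_s": r.start_s, "end_s": r.end_s, "peak_s": r.peak_s,
                  "peak_power": r.peak_power, "duration_ms": r.duration_ms}
                 for r in ripples])
            lfp_summary = {"n_ripples": len(ripples)}
            rng_lfp = rngs["lfp_shuffles"]
            if ripples:
                mod_rows = []
                for cid, train in spike_trains.items():
                    try:
                        idx, p = lfpmod.ripple_modulation_index(
                            train, ripples, duration,
                            rc.n_shuffles_modulation, seed=rng_lfp)
                    except lfpmod.UndefinedIndexError:
                        idx, p = np.nan, np.nan
                    mod_rows.append({"cell_or_session": cid, "index_or_strength": idx,
                                     "preferred_phase_deg": np.nan, "p_value": p})
                tables["ripple_modulation"] = pd.DataFrame(mod_rows)
                vals = [r["index_or_strength"] for r in mod_rows
                        if np.isfinite(r["index_or_strength"])]
                lfp_summary["median_ripple_modulation"] = (
                    float(np.median(vals)) if vals else None)
                if events is not None and events.n_events:
                    s2r, r2s, _ = lfpmod.co_occurrence(
                        events.event_times, [(r.start_s, r.end_s) for r in ripples])
                    lfp_summary["pct_ripples_with_sync"] = s2r
                    lfp_summary["pct_sync_in_ripples"] = r2s
            if events is not None and events.n_events:
                ps = lfpmod.phase_series(bundle.lfp.samples, lfp_fs, rc.theta_band_hz)
                mod = lfpmod.event_phase_modulation(
                    events.event_times, ps, duration,
                    rc.n_shuffles_modulation, seed=rng_lfp)
                lfp_summary["theta_modulation_strength"] = mod.strength
                lfp_summary["theta_preferred_phase_deg"] = float(
                    np.degrees(mod.preferred_phase))
                lfp_summary["theta_modulation_p"] = mod.p_value
                centers, hist, dev = lfpmod.phase_deviation_histogram(
                    events.event_times, ps, mod.preferred_phase)
                lfp_summary["pct_within_30deg"] = 100.0 * float(
                    np.mean(np.abs(dev) <= 30.0))
                mean_trace, _, _ = lfpmod.triggered_average(
                    bundle.lfp.samples, lfp_fs, events.event_times,
                    rc.triggered_lfp_halfwidth_s)
                freqs, power = lfpmod.psd_fft(mean_trace, lfp_fs)
                theta_sel = (freqs >= rc.theta_band_hz[0]) & (freqs <= rc.theta_band_hz[1])
                lfp_summary["triggered_lfp_peak_freq_hz"] = float(
                    freqs[theta_sel][np.argmax(power[theta_sel])])
            report["lfp"] = lfp_summary
        except Exception as e:  # noqa: BLE001
            raise StageError("lfp", e) from e

    # --- subvm ----------------------------------------------------------
    if stage_on("subvm") and spike_trains:
        try:
            segments = sub.label_segments(bundle.behavior.speed_cm_s, fs)
            subvms = {a.cell_id: a.subvm for a in activities
                      if a.cell_id in included}
            sub_summary = {}
            if events is not None and events.n_events:
                _, grand, omitted = sub.synchrony_triggered_subvm(
                    subvms, spike_trains, events.event_times, fs,
                    rc.subvm_halfwidth_s)
                mid = grand.size // 2
                sub_summary["triggered_peak_minus_mean"] = float(
                    grand[mid] - grand.mean())
                sub_summary["n_cells_omitted"] = len(omitted)
            rows = []
            ids = sorted(subvms)
            for a_id, b_id in itertools.combinations(ids, 2):
                coh, counts, _ = sub.pairwise_theta_coherence(
                    subvms[a_id], subvms[b_id], segments, rc.theta_band_hz)
                lags, xc, _ = sub.pairwise_subvm_xcorr(
                    subvms[a_id], subvms[b_id], segments)
                d = float(np.linalg.norm(centroids[a_id] - centroids[b_id]))
                for state in coh:
                    peak_i = int(np.argmax(xc[state])) if state in xc else None
                    rows.append({
                        "cell_a": a_id, "cell_b": b_id, "state": state,
                        "theta_coherence": coh[state],
                        "xcorr_peak": float(xc[state][peak_i]) if peak_i is not None else np.nan,
                        "xcorr_peak_lag_ms": float(lags[peak_i] * 1000.0)
                        if peak_i is not None else np.nan,
                        "soma_distance_um": d,
                    })
            tables["subvm_pairs"] = pd.DataFrame(rows)
            for state in ("immobility", "locomotion"):
                sel = [r for r in rows if r["state"] == state]
                if len(sel) >= 3:
                    try:
                        rho, _ = sub.coherence_vs_distance(
                            [r["theta_coherence"] for r in sel],
                            [r["soma_distance_um"] for r in sel])
                    except ValueError:
                        rho = np.nan
                    sub_summary[f"coherence_distance_rho_{state}"] = rho
                    sub_summary[f"median_theta_coherence_{state}"] = float(
                        np.median([r["theta_coherence"] for r in sel]))
            report["subvm"] = sub_summary
        except Exception as e:  # noqa: BLE001
            raise StageError("subvm", e) from e

    # --- spatial ----------------------------------------------------------
    if stage_on("spatial") and spike_trains:
        try:
            curves = {}
            for cid, train in spike_trains.items():
                try:
                    curves[cid] = spa.tuning_curve(
                        train, bundle.behavior, rc.n_bins_spatial,
                        bundle.behavior.track_length_cm,
                        sampling_rate_hz=fs)
                except spa.UndefinedCurveError:
                    continue
            tables["tuning"] = spa.tuning_table(curves)
            tables["place_cells"] = spa.place_cell_summary(curves)
            pc_ids = sorted(cid for cid, c in curves.items() if c.is_place_cell)
            spatial_summary = {
                "n_place_cells": len(pc_ids),
                "place_cell_fraction": len(pc_ids) / len(spike_trains)
                if spike_trains else None,
            }
            pairs = []
            for a_id, b_id in itertools.combinations(pc_ids, 2):
                key = (a_id, b_id, "locomotion")
                if key not in pair_results:
                    continue
                try:
                    sim = spa.tuning_similarity(curves[a_id], curves[b_id])
                except ValueError:
                    continue
                pairs.append((pair_results[key].sync_strength, sim))
            if len(pairs) >= 5:
                rho, p = spa.synchrony_vs_tuning(
                    pairs, rc.n_permutations_spatial, seed=rngs["spatial_perm"])
                spatial_summary["sync_vs_tuning_rho"] = rho
                spatial_summary["sync_vs_tuning_p"] = p
                spatial_summary["n_place_pairs"] = len(pairs)
            report["spatial"] = spatial_summary
        except Exception as e:  # noqa: BLE001
            raise StageError("spatial", e) from e

    if rc.out_dir:
        os.makedirs(rc.out_dir, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(os.path.join(rc.out_dir, f"{name}.csv"), index=False)
        with open(os.path.join(rc.out_dir, "summary.json"), "w") as fh:
            json.dump(_jsonable(report), fh, sort_keys=True, indent=1)
        with open(os.path.join(rc.out_dir, "run_log.txt"), "w") as fh:
            fh.write(f"voltsync {__version__}\nmaster_seed {rc.master_seed}\n"
                     f"stages {','.join(rc.stages)}\n"
                     f"params {json.dumps(_jsonable(rc.__dict__), sort_keys=True)}\n")
    report["_tables"] = tables
    return report


def summary_json(report: dict) -> str:
    """Deterministic JSON rendering of a report (tables stripped)."""
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(_jsonable(clean), sort_keys=True, indent=1)


def match_events(detected: np.ndarray, truth: np.ndarray, tol_s: float):
    """Greedy one-to-one matching of detected to true event times.

    Returns (hits, precision, recall).
    """
    detected = np.sort(np.asarray(detected, dtype=float))
    truth = np.sort(np.asarray(truth, dtype=float))
    used = np.zeros(truth.size, dtype=bool)
    hits = 0
    for t in detected:
        if truth.size == 0:
            break
        i = int(np.argmin(np.where(used, np.inf, np.abs(truth - t))))
        if not used[i] and abs(truth[i] - t) <= tol_s:
            used[i] = True
            hits += 1
    precision = hits / detected.size if detected.size else 0.0
    recall = hits / truth.size if truth.size else 0.0
    return hits, precision, recall


def compare_to_truth(bundle: SessionBundle, report: dict, truth: GroundTruth,
                     activities: list | None = None) -> pd.DataFrame:
    """Score pipeline detections against the generator ledger.

    Covers spikes (±1 ms), synchrony events (±12.5 ms), ripples (±10 ms on
    boundaries) and place-field centers.
    """
    if not bundle.session_id.startswith("synthetic"):
        raise ValueError("truth comparison requires a synthetic session")
    rows = []
    spikes_tbl = report["_tables"].get("spikes")
    if spikes_tbl is not None:
        for cid, true_t in truth.true_spikes.items():
            det = spikes_tbl[spikes_tbl.cell_id == cid].spike_time_s.to_numpy()
            _, prec, rec = match_events(det, true_t, 0.001)
            rows.append({"quantity": f"spikes_{cid}", "precision": prec,
                         "recall": rec, "error": np.nan})
    ev_tbl = report["_tables"].get("sync_events")
    if ev_tbl is not None and truth.true_sync_times.size:
        _, prec, rec = match_events(ev_tbl.event_time_s.to_numpy(),
                                    truth.true_sync_times, 0.0125)
        rows.append({"quantity": "sync_events", "precision": prec,
                     "recall": rec, "error": np.nan})
    rip_tbl = report["_tables"].get("ripples")
    if rip_tbl is not None and truth.true_ripples:
        true_peaks = np.asarray([(s + e) / 2 for s, e in truth.true_ripples])
        _, prec, rec = match_events(rip_tbl.peak_s.to_numpy(), true_peaks, 0.05)
        rows.append({"quantity": "ripples", "precision": prec, "recall": rec,
                     "error": np.nan})
    pc_tbl = report["_tables"].get("tuning")
    if pc_tbl is not None:
        errs = []
        for cid, center in truth.true_fields.items():
            if center is None:
                continue
            cur = pc_tbl[pc_tbl.cell_id == cid]
            if not len(cur):
                continue
            best = cur.loc[cur.rate_hz.idxmax()]
            d = abs(best.bin_center_cm - center)
            errs.append(min(d, 90.0 - d))
        if errs:
            rows.append({"quantity": "field_center_error_cm",
                         "precision": np.nan, "recall": np.nan,
                         "error": float(np.median(errs))})
    return pd.DataFrame(rows)
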