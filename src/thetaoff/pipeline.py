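"""End-to-end in vivo pipeline: session(s) -> profiles, classes, events, report.

Mirrors the two-session imaging design: per cell, state-dependent peak
statistics are computed for each 5-min session (S1, S2) and averaged (AVG);
the per-cell AVG immobility/locomotion ratio feeds the Otsu classification.
The LFP of each session contributes theta-run epochs and ripple events, and
each cell's dF/F is segmented around the event onsets.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import IMMOBILITY, LOCOMOTION, BehaviorSegmentation, SegmentationParams, segment_states
from .calcium import (
    classification_feature,
    compute_dff,
    detect_transients,
    otsu_classify,
    state_peak_stats,
)
from .lfp import (
    RIPPLE_BAND,
    THETA_BAND,
    detect_ripples,
    detect_theta_run_epochs,
    event_triggered_segments,
    state_modulation_test,
)
from .synth.session import SyntheticSession


@dataclass
class RunConfig:
    sessions: list = field(default_factory=list)  # paths or SyntheticSession objects
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    transient_k_sd: float = 3.0
    peak_window_ms: float = 315.0
    feature_mode: str = "ratio"
    ripple_threshold_sd: float = 5.0
    eta_window_s: tuple[float, float] = (2.0, 5.0)
    seed: int = 0
    out_dir: str | Path | None = None


@dataclass
class AnalysisReport:
    profiles: pd.DataFrame
    classes: pd.DataFrame | None
    eta: float | None
    ripples: pd.DataFrame
    theta_epochs: pd.DataFrame
    event_triggered: dict
    group_stats: dict
    provenance: dict


def _load(session) -> SyntheticSession:
    if isinstance(session, SyntheticSession):
        return session
    from .io import read_session

    return read_session(session)


def _profile_session(
    session: SyntheticSession, config: RunConfig
) -> tuple[BehaviorSegmentation, dict]:
    seg = segment_states(session.speed, config.segmentation)
    profiles = {}
    for trace in session.ca_traces:
        dff = compute_dff(trace)
        peaks = detect_transients(dff, k_sd=config.transient_k_sd)
        prof = state_peak_stats(
            dff, seg, peaks, window_ms=config.peak_window_ms, cell_id=trace.name
        )
        profiles[trace.name] = (dff, prof)
    return seg, profiles


def run_invivo_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute the full pipeline on one or two sessions.

    Stages: behaviour segmentation -> dF/F -> transient peak statistics per
    state -> Otsu classification of the per-cell AVG feature -> theta-run and
    ripple events -> event-triggered dF/F averages -> group rank tests.
    A session without an LFP yields an imaging-only report.
    """
    if not config.sessions:
        raise ValueError("config.sessions is empty")
    sessions = [_load(s) for s in config.sessions[:2]]
    per_session = []
    for k, sess in enumerate(sessions):
        try:
            per_session.append(_profile_session(sess, config))
        except Exception as exc:  # stage-tagged failure
            raise RuntimeError(f"imaging stage failed on session {k + 1}: {exc}") from exc

    # --- per-cell state table over sessions -------------------------------
    cell_ids = [t.name for t in sessions[0].ca_traces]
    rows = []
    avg_by_cell: dict[str, dict[str, float]] = {}
    for cell in cell_ids:
        entry: dict[str, float] = {}
        for k, (_, profiles) in enumerate(per_session):
            if cell not in profiles:
                continue
            prof = profiles[cell][1]
            for state in (LOCOMOTION, IMMOBILITY):
                if state in prof.states:
                    st = prof.states[state]
                    rows.append(
                        {
                            "cell_id": cell,
                            "session": f"S{k + 1}",
                            "state": state,
                            "mean_peak_dff": st.mean_peak_dff,
                            "n_periods": st.n_periods,
                            "n_transients": st.n_transients,
                        }
                    )
        df_cell = pd.DataFrame([r for r in rows if r["cell_id"] == cell])
        for state in (LOCOMOTION, IMMOBILITY):
            vals = df_cell[df_cell["state"] == state]["mean_peak_dff"]
            if len(vals):
                entry[state] = float(vals.mean())
        avg_by_cell[cell] = entry
        for state, v in entry.items():
            rows.append(
                {
                    "cell_id": cell,
                    "session": "AVG",
                    "state": state,
                    "mean_peak_dff": v,
                    "n_periods": 0,
                    "n_transients": 0,
                }
            )
    profiles_df = pd.DataFrame(rows)

    # --- classification ---------------------------------------------------
    feats, feat_cells = [], []
    for cell, entry in avg_by_cell.items():
        if LOCOMOTION in entry and IMMOBILITY in entry:
            feats.append(classification_feature(entry, mode=config.feature_mode))
            feat_cells.append(cell)
        else:
            warnings.warn(
                f"cell {cell} lacks transients in one state; excluded from "
                "classification",
                stacklevel=2,
            )
    classes_df, eta = None, None
    if len(feats) >= 2 and np.ptp(feats) > 0:
        cls = otsu_classify(np.asarray(feats), feat_cells)
        eta = cls.eta
        classes_df = pd.DataFrame(
            {
                "cell_id": cls.cell_ids,
                "feature": cls.features,
                "label": cls.labels,
                "threshold": cls.threshold,
                "eta": cls.eta,
            }
        )

    # --- LFP events + event-triggered averages (session 1) ----------------
    ripples_df = pd.DataFrame()
    theta_df = pd.DataFrame()
    event_triggered: dict = {}
    group_stats: dict = {}
    sess0 = sessions[0]
    seg0, profiles0 = per_session[0]
    if sess0.lfp is not None:
        try:
            ripples = detect_ripples(
                sess0.lfp,
                RIPPLE_BAND,
                threshold_sd=config.ripple_threshold_sd,
                segmentation=seg0,
            )
            ripples_df = pd.DataFrame(
                [
                    {
                        "t_start_s": r.t_start_s,
                        "t_end_s": r.t_end_s,
                        "t_peak_s": r.t_peak_s,
                        "duration_ms": r.duration_ms,
                        "peak_freq_hz": r.peak_freq_hz,
                        "peak_amplitude_sd": r.peak_amplitude_sd,
                    }
                    for r in ripples
                ]
            )
            theta_epochs = detect_theta_run_epochs(sess0.lfp, seg0)
            theta_df = pd.DataFrame(
                [
                    {
                        "t_onset_s": e.t_onset_s,
                        "t_end_s": e.t_end_s,
                        "theta_power": e.theta_power,
                        "theta_peak_hz": e.theta_peak_hz,
                        "power_above_immobility": e.power_above_immobility,
                    }
                    for e in theta_epochs
                ]
            )
            for cell, (dff, _) in profiles0.items():
                etas = {}
                if len(theta_df):
                    try:
                        etas["theta_run"] = event_triggered_segments(
                            dff.dff,
                            theta_df["t_onset_s"].to_numpy(),
                            window_s=config.eta_window_s,
                        )
                    except ValueError:
                        pass
                if len(ripples_df):
                    try:
                        etas["ripple"] = event_triggered_segments(
                            dff.dff,
                            ripples_df["t_start_s"].to_numpy(),
                            window_s=(1.0, 1.0),
                            event_end_times_s=ripples_df["t_end_s"].to_numpy(),
                        )
                    except ValueError:
                        pass
                event_triggered[cell] = etas
        except Exception as exc:
            raise RuntimeError(f"LFP stage failed: {exc}") from exc
    else:
        group_stats["lfp"] = "absent"

    # --- group statistics -------------------------------------------------
    for cell, (_, prof) in profiles0.items():
        if LOCOMOTION in prof.states and IMMOBILITY in prof.states:
            stat, p = state_modulation_test(
                prof.states[IMMOBILITY].period_means,
                prof.states[LOCOMOTION].period_means,
            )
            group_stats[cell] = {"U": stat, "p": p}

    provenance = {
        "seed": config.seed,
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "transient_k_sd": config.transient_k_sd,
                    "peak_window_ms": config.peak_window_ms,
                    "feature_mode": config.feature_mode,
                    "ripple_threshold_sd": config.ripple_threshold_sd,
                    "seed": config.seed,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16],
    }

    report = AnalysisReport(
        profiles=profiles_df,
        classes=classes_df,
        eta=eta,
        ripples=ripples_df,
        theta_epochs=theta_df,
        event_triggered=event_triggered,
        group_stats=group_stats,
        provenance=provenance,
    )
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    return report


def write_report(report: AnalysisReport, out_dir: str | Path) -> None:
    """Write CSV tables, summary figures and a markdown summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.profiles.to_csv(out / "profiles.csv", index=False)
    if report.classes is not None:
        report.classes.to_csv(out / "classes.csv", index=False)
    report.ripples.to_csv(out / "ripples.csv", index=False)
    report.theta_epochs.to_csv(out / "theta.csv", index=False)

    lines = ["# Session analysis report", ""]
    lines.append(f"- provenance: {report.provenance}")
    if report.eta is not None:
        n1 = sum(report.classes["label"] == "type_I")
        n2 = sum(report.classes["label"] == "type_II")
        lines.append(
            f"- Otsu classification: eta = {report.eta:.3f}, "
            f"{n1} type I / {n2} type II cells"
        )
    if len(report.theta_epochs):
        lines.append(
            f"- theta-run epochs: {len(report.theta_epochs)}, median peak "
            f"{report.theta_epochs['theta_peak_hz'].median():.2f} Hz"
        )
    if len(report.ripples):
        lines.append(
            f"- ripples: {len(report.ripples)}, mean peak frequency "
            f"{report.ripples['peak_freq_hz'].mean():.1f} Hz"
        )
    if "lfp" in report.group_stats:
        lines.append("- LFP: absent; event sections skipped")
    (out / "summary.md").write_text("\n".join(lines) + "\n")
    _write_figures(report, out)


def _write_figures(report: AnalysisReport, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.classes is not None and len(report.profiles):
        avg = report.profiles[report.profiles["session"] == "AVG"]
        pivot = avg.pivot_table(index="cell_id", columns="state", values="mean_peak_dff")
        order = report.classes.sort_values("feature", ascending=False)["cell_id"]
        pivot = pivot.reindex([c for c in order if c in pivot.index])
        fig, ax = plt.subplots(figsize=(4, 0.25 * len(pivot) + 1.5))
        im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(pivot.columns)), pivot.columns)
        ax.set_yticks(range(len(pivot)), pivot.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="mean peak %dF/F")
        fig.tight_layout()
        fig.savefig(out / "class_heatmap.png", dpi=120)
        plt.close(fig)

    panels = [
        (cell, kind, eta)
        for cell, etas in report.event_triggered.items()
        for kind, eta in etas.items()
    ]
    if panels:
        fig, axes = plt.subplots(
            1, min(len(panels), 6), figsize=(3 * min(len(panels), 6), 2.5), squeeze=False
        )
        for ax, (cell, kind, eta) in zip(axes[0], panels):
            ax.plot(eta.lags_s, eta.aligned_traces.T, color="0.8", lw=0.5)
            ax.plot(eta.lags_s, eta.mean_trace, color="crimson", lw=1.5)
            ax.axvline(0.0, color="k", ls=":", lw=0.8)
            ax.set_title(f"{cell}: {kind} (n={eta.n_events})", fontsize=8)
            ax.set_xlabel("time from onset (s)")
        axes[0][0].set_ylabel("%dF/F")
        fig.tight_layout()
        fig.savefig(out / "event_triggered.png", dpi=120)
        plt.close(fig)
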