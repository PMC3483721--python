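"""Run manifests and figure/table regeneration.

Every CLI command writes its outputs plus a ``manifest.json`` (config echo,
seed, package version, timestamp, file checksums) into one directory;
:func:`make_report` re-renders standard figures from whatever outputs are
present, skipping the rest with a notice.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__

logger = logging.getLogger("gatingrl")

MANIFEST_NAME = "manifest.json"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: Path, command: str, config: dict, seed: int | None) -> Path:
    """Write the directory's manifest, checksumming every other file in it."""
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.iterdir()
                   if p.is_file() and p.name != MANIFEST_NAME)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "version": __version__,
        "created": datetime.now(timezone.utc).isoformat(),
        "outputs": {p.name: _sha256(p) for p in files},
    }
    path = out_dir / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(run_dir: Path) -> dict:
    return json.loads((Path(run_dir) / MANIFEST_NAME).read_text())


def value_tables_frame(tables) -> pd.DataFrame:
    """Value tables as one matrix: 16 'observation|memory' rows, one column
    per motor/gating action (plus V for Actor-Critic variants)."""
    from .rl_core import GATING_ACTIONS, N_STATES, state_label
    from .task_env import MOTOR_ACTIONS

    data = {}
    for j, name in enumerate(MOTOR_ACTIONS):
        data[f"Q_motor[{name}]"] = tables.q_motor[:, j]
    for j, name in enumerate(GATING_ACTIONS):
        data[f"Q_gating[{name}]"] = tables.q_gating[:, j]
    if tables.v is not None:
        data["V"] = tables.v
    return pd.DataFrame(data, index=[state_label(s) for s in range(N_STATES)])


def trial_logs_frame(logs) -> pd.DataFrame:
    """Tidy per-step table (trial, step, observation, memory, actions,
    reward) from a list of :class:`TrialLog` records."""
    from .rl_core import GATING_ACTIONS, MEMORY_CONTENTS
    from .task_env import MOTOR_ACTIONS, OBSERVATIONS

    rows = []
    for t, log in enumerate(logs):
        for step in log.steps:
            rows.append({
                "trial": t,
                "step": step.step_index,
                "observation": OBSERVATIONS[step.observation],
                "memory": MEMORY_CONTENTS[step.memory],
                "motor_action": MOTOR_ACTIONS[step.motor_action],
                "gating_action": GATING_ACTIONS[step.gating_action],
                "reward": step.reward,
            })
    return pd.DataFrame(rows)


def _save(fig, path: Path) -> Path:
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    logger.info("wrote %s", path)
    return path


def plot_learning_curves(curves: pd.DataFrame, path: Path,
                         title: str = "Average learning curve") -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    x = curves["session"]
    mean, sd = curves["mean_accuracy"], curves["sd_accuracy"]
    ax.plot(x, mean, color="C0", label="mean accuracy")
    ax.fill_between(x, mean - sd, mean + sd, color="C0", alpha=0.25,
                    label="$\\pm$1 SD")
    ax.axhline(0.5, color="grey", ls=":", lw=1)
    ax.set(xlabel="session", ylabel="fraction correct", ylim=(0, 1), title=title)
    ax.legend(frameon=False)
    return _save(fig, path)


def plot_kl_vs_n(fits: list[dict], path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    ns = [f["n_central"] for f in fits]
    kls = [f["kl"] for f in fits]
    ax.plot(ns, kls, "o-", color="C1")
    ax.set(xlabel="central-arm observations $n$", ylabel="minimum KL divergence",
           title="Fit quality vs. task depth")
    return _save(fig, path)


def plot_transfer(runs: pd.DataFrame, path: Path) -> Path:
    """Box plot of pre- vs post-reversal sessions to the 80% criterion.

    Whiskers extend to the furthest points within 1.5 IQR of the quartiles;
    points beyond are drawn as outliers.
    """
    fig, ax = plt.subplots(figsize=(4, 4))
    data = [runs["pre_sessions_to_80"].dropna(), runs["post_sessions_to_80"].dropna()]
    ax.boxplot(data, tick_labels=["pre", "post"], whis=1.5,
               flierprops={"marker": ".", "markerfacecolor": "black"})
    ax.set(ylabel="sessions to 80% criterion", title="Reversal transfer")
    return _save(fig, path)


def plot_strategy_frequencies(summary: dict, path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    pct = summary["percentages"]
    labels = list(pct)
    ax.bar(labels, [pct[l] for l in labels], color="C2")
    ax.set(ylabel="% of runs", title="Learned strategy frequencies")
    ax.tick_params(axis="x", rotation=20)
    return _save(fig, path)


def make_report(run_dir: Path) -> dict:
    """Render every figure whose inputs exist in ``run_dir``.

    Returns ``{"written": [...], "skipped": [...]}``; missing inputs are
    reported per figure, never fatally.
    """
    run_dir = Path(run_dir)
    written, skipped = [], []

    curves_csv = run_dir / "curves.csv"
    if curves_csv.exists():
        written.append(plot_learning_curves(pd.read_csv(curves_csv),
                                            run_dir / "learning_curves.png"))
    else:
        skipped.append("learning_curves.png (no curves.csv)")

    fits_json = run_dir / "fits.json"
    if fits_json.exists():
        fits = json.loads(fits_json.read_text())
        written.append(plot_kl_vs_n(fits, run_dir / "kl_vs_n.png"))
    else:
        skipped.append("kl_vs_n.png (no fits.json)")

    runs_csv = run_dir / "runs.csv"
    if runs_csv.exists():
        runs = pd.read_csv(runs_csv)
        if {"pre_sessions_to_80", "post_sessions_to_80"} <= set(runs.columns):
            written.append(plot_transfer(runs, run_dir / "transfer_box.png"))
        else:
            skipped.append("transfer_box.png (runs.csv has no reversal columns)")
    else:
        skipped.append("transfer_box.png (no runs.csv)")

    summary_json = run_dir / "strategy_summary.json"
    if summary_json.exists():
        summary = json.loads(summary_json.read_text())
        written.append(plot_strategy_frequencies(summary,
                                                 run_dir / "strategy_frequencies.png"))
    else:
        skipped.append("strategy_frequencies.png (no strategy_summary.json)")

    for note in skipped:
        logger.info("skipped %s", note)
    return {"written": [str(p) for p in written], "skipped": skipped}
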