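"""End-to-end orchestration: simulate/load -> bin -> screen -> sequences ->
decode -> psychometrics -> PCA, with a JSON summary report.

Every stage's seed is derived deterministically from the master seed, so a
run is reproducible end to end; all thresholds are echoed into the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binning, decoding, neurometrics, screening, sequences, statespace
from .session import Session, epoch_defaults, load_session
from .synthetic import make_population

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "compare_regions"]

CONTRASTS = ("stimulus", "choice", "outcome")


@dataclass
class RunConfig:
    session_path: str | None = None     # load a session, or ...
    template: str = "encoders_mixed"    # ... generate one from a template
    seed: int = 0
    n_trials: int | None = None
    n_perm: int = 2000                  # screening permutations
    alpha: float = 0.05
    min_run: int = 5
    reproducibility_n_perm: int = 2000
    decode_bin_step: int = 10           # decode every k-th sliding bin
    pca_components: int = 3
    out_dir: str | None = None

    def stage_seed(self, stage: str) -> int:
        # stable per-stage split of the master seed, kept below 2**31
        import zlib
        tag = zlib.crc32(stage.encode())
        return int(np.random.SeedSequence(
            (self.seed, tag)).generate_state(1)[0] % (2**31))


def _screen(session: Session, contrast: str, cfg: RunConfig):
    epoch = epoch_defaults(contrast)
    mask, labels = screening.contrast_labels(session, contrast)
    keep = {t.trial_id for t, m in zip(session.trials, mask) if m}
    tensor = binning.sliding_rates(session, epoch,
                                   trial_filter=lambda t: t.trial_id in keep)
    label_of = {t.trial_id: lab
                for t, lab in zip([t for t, m in zip(session.trials, mask) if m],
                                  labels)}
    lab = np.asarray([label_of[tid] for tid in tensor.trial_ids], bool)
    choice = None
    if contrast == "stimulus":
        by_id = {t.trial_id: t.choice == "sucrose" for t in session.trials}
        choice = np.asarray([by_id[tid] for tid in tensor.trial_ids], bool)
    sm = screening.selectivity_matrix(
        tensor, lab, contrast, n_perm=cfg.n_perm,
        seed=cfg.stage_seed(f"screen-{contrast}"), choice_labels=choice,
        alpha=cfg.alpha)
    return tensor, lab, sm


def run_all(config: RunConfig) -> dict:
    """Execute every stage on one session; return (and optionally write)
    the summary report."""
    cfg = config
    if cfg.session_path:
        session = load_session(cfg.session_path)
        truth = None
    else:
        session, truth = make_population(cfg.template, seed=cfg.seed,
                                         n_trials=cfg.n_trials)

    report: dict = {
        "session_id": session.session_id,
        "region": session.region,
        "n_trials": session.n_trials,
        "n_neurons": session.n_neurons,
        "parameters": {
            "seed": cfg.seed, "n_perm": cfg.n_perm, "alpha": cfg.alpha,
            "min_run": cfg.min_run, "auroc_margin": screening.AUROC_MARGIN,
            "class_orientation": "low=water/water_response/non_rewarded, "
                                 "high=sucrose/sucrose_response/rewarded",
        },
        "contrasts": {},
    }

    # behavior
    emp = neurometrics.empirical_psychometric(session)
    try:
        fit = neurometrics.fit_power_psychometric(
            emp["concentration"].to_numpy(), emp["p_sucrose"].to_numpy())
        report["psychometric"] = dict(a=fit.a, b=fit.b, r2=fit.r2,
                                      threshold_pct=fit.threshold)
    except (ValueError, RuntimeError) as exc:    # degenerate behavior
        logger.warning("psychometric fit failed: %s", exc)
        report["psychometric"] = None

    tensors = {}
    encoder_masks = {}
    for contrast in CONTRASTS:
        tensor, labels, sm = _screen(session, contrast, cfg)
        enc = screening.detect_encoders(sm, min_run=cfg.min_run)
        tensors[contrast] = (tensor, labels, sm, enc)
        encoder_masks[contrast] = enc.is_encoder
        entry: dict = {
            "n_encoders": enc.n_encoders,
            "n_neurons": int(len(sm.neuron_ids)),
            "percent": round(enc.n_encoders / len(sm.neuron_ids) * 100, 2),
            "preferences": {
                k: int((enc.preference == k).sum())
                for k in ("classA_preferring", "classB_preferring", "switching")
            },
        }
        if enc.n_encoders >= 2:
            enc_sm = sm.restrict_neurons(enc.is_encoder)
            try:
                sq = sequences.sequentiality(enc_sm)
                entry["sequentiality"] = dict(PE=sq.PE, TS=sq.TS, SqI=sq.SqI,
                                              N=sq.N, B=sq.B)
                R, kept_centers = sequences.rectify(enc_sm)
                active = R.any(axis=1)
                entry["peak_times_ms"] = [
                    float(kept_centers[b])
                    for b in np.argmax(R[active], axis=1)]
            except sequences.DegenerateMatrixError as exc:
                logger.warning("%s sequentiality degenerate: %s", contrast, exc)
            rep = sequences.split_half_reproducibility(
                tensor, labels, n_perm=cfg.reproducibility_n_perm,
                seed=cfg.stage_seed(f"split-{contrast}"))
            entry["reproducibility"] = dict(mse=rep.mse, p=rep.p)
        report["contrasts"][contrast] = entry

    # binary stimulus decoding on the stimulus-encoding subset
    tensor, labels, sm, enc = tensors["stimulus"]
    if enc.n_encoders >= 2:
        dcfg = decoding.DecodingConfig(schema="binary", kernel="linear",
                                       seed=cfg.stage_seed("decode"))
        bins = np.arange(0, tensor.epoch.n_bins, cfg.decode_bin_step)
        sub = tensor.rates[enc.is_encoder]
        res = decoding.decode(sub, labels.astype(int), dcfg,
                              tensor.bin_centers, bins=bins)
        ctrl = decoding.decode(sub, labels.astype(int),
                               dataclasses.replace(dcfg, permute_labels=True),
                               tensor.bin_centers, bins=bins)
        report["decoding"] = dict(
            schema="binary", kernel="linear",
            bin_centers=[float(c) for c in res.bin_centers],
            mean_accuracy=[float(a) for a in res.mean_accuracy],
            control_accuracy=[float(a) for a in ctrl.mean_accuracy],
            peak_accuracy=float(res.mean_accuracy.max()),
            control_mean=float(ctrl.accuracy.mean()),
        )

    # PCA on stimulus-aligned, concentration-averaged smoothed rates
    sm_rates = binning.kernel_rates(
        session, "stimulus_delivery_t", (-200.0, 800.0),
        lambda tr: tr.stimulus.concentration, min_trials=2)
    mat, conds, _ = statespace.condition_matrix(sm_rates)
    ts = statespace.pca_trajectories(mat, conds, sm_rates.t_grid)
    dists = statespace.trajectory_distances(
        ts, statespace.water_sucrose_pairs(conds),
        n_components=cfg.pca_components)
    report["pca"] = dict(
        explained_variance=[float(v) for v in ts.explained_variance[:5]],
        water_sucrose_peak_distance=float(dists.mean.max()),
    )

    if truth is not None:
        report["ground_truth_counts"] = (
            truth.groupby("tuned_variable").size().to_dict())

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True) + "\n")
        for contrast, (_, _, smx, encx) in tensors.items():
            encx.table().to_csv(out / f"encoders_{contrast}.tsv", sep="\t",
                                index=False)
    return report


def compare_regions(report_a: dict, report_b: dict) -> pd.DataFrame:
    """Cross-region comparison: encoder-proportion z-tests and latency KS."""
    from scipy import stats

    rows = []
    for contrast in CONTRASTS:
        ca = report_a["contrasts"].get(contrast)
        cb = report_b["contrasts"].get(contrast)
        if ca is None or cb is None:
            continue
        z, p = screening.proportion_ztest(ca["n_encoders"], ca["n_neurons"],
                                          cb["n_encoders"], cb["n_neurons"])
        row = dict(contrast=contrast,
                   k1=ca["n_encoders"], n1=ca["n_neurons"],
                   k2=cb["n_encoders"], n2=cb["n_neurons"],
                   z=round(z, 3), p=round(p, 3),
                   ks_D=np.nan, ks_p=np.nan)
        pa, pb = ca.get("peak_times_ms"), cb.get("peak_times_ms")
        if pa and pb and len(pa) >= 3 and len(pb) >= 3:
            res = stats.ks_2samp(pa, pb)
            row["ks_D"] = round(float(res.statistic), 3)
            row["ks_p"] = round(float(res.pvalue), 4)
        rows.append(row)
    return pd.DataFrame(rows)
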