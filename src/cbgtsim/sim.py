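"""End-to-end simulation of one agent in one environment."""

from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd

from .build import build_network
from .config import Configuration, validate_config
from .engine import RealizedNetwork
from .environment import TraceRecorder, TrialPhaseConfig, generate_reward_schedule, run_trial
from .plasticity import PlasticityParams, QState, WeightState, update_q, update_weights

__all__ = ["ResultsBundle", "simulate_one"]


class ResultsBundle(dict):
    """Keyed record with everything a simulation produced.

    Contains the echo of every configuration value passed in, plus
    ``popfreqs`` (population rate traces), ``datatables`` (per-trial
    behavior), ``Q_df`` (action values over trials), ``recorded_variables``
    (weight / stimulation traces when requested), ``seed`` and run
    metadata.
    """


def simulate_one(config: Configuration | dict[str, Any], seed: int | None = None) -> ResultsBundle:
    """Run one full simulation under one seed and assemble its results."""
    if not isinstance(config, Configuration):
        config = validate_config(config)
    if seed is None:
        seed = config.seed
    seed = int(seed)
    rng = np.random.default_rng(seed)

    net: RealizedNetwork = build_network(
        config.paramfile,
        config.channels,
        newpathways=config.newpathways,
        seed=seed,
        task=config.experimentchoice,
    )
    schedule = generate_reward_schedule(
        config.conflict,
        config.volatility,
        config.n_trials,
        config.reward_mu,
        config.reward_std,
        rng=rng,
    )
    phase_cfg = TrialPhaseConfig(
        thalamic_threshold=config.thalamic_threshold,
        choice_timeout=config.choice_timeout,
        movement_time=config.movement_time,
        inter_trial_interval=config.inter_trial_interval,
        sustainedfraction=config.sustainedfraction,
        maxstim=config.maxstim,
    )
    for proto in config.protocols:
        proto.realize(config.channels, config.n_trials, rng)

    dspn_params = PlasticityParams(
        dpmn_alphaw=float(config.paramfile["dSPNdefaults"]["dpmn_alphaw"]),
        dpmn_wmax=float(config.paramfile["dSPNdefaults"]["dpmn_wmax"]),
        dpmn_tauDOP=float(config.paramfile["dpmndefaults"]["dpmn_tauDOP"]),
        dpmn_baseline=float(config.paramfile["dpmndefaults"].get("dpmn_baseline", 0.0)),
    )
    ispn_params = PlasticityParams(
        dpmn_alphaw=float(config.paramfile["iSPNdefaults"]["dpmn_alphaw"]),
        dpmn_wmax=float(config.paramfile["iSPNdefaults"]["dpmn_wmax"]),
        dpmn_tauDOP=float(config.paramfile["dpmndefaults"]["dpmn_tauDOP"]),
        dpmn_baseline=float(config.paramfile["dpmndefaults"].get("dpmn_baseline", 0.0)),
    )
    qstate = QState.initial(config.channels, q_alpha=config.q_alpha, C_scale=config.C_scale)
    qstate.q.update(config.q0)
    weights = WeightState(w=dict(net.weights))

    recorder = TraceRecorder(net, config.record_variables)
    recorder.record_weights(trial=-1)

    records = []
    q_rows = [dict(qstate.q)]
    for trial in range(config.n_trials):
        rec = run_trial(net, trial, schedule, phase_cfg, config.protocols, rng, recorder)
        if config.corticostriatal_plasticity_present and rec.decision != "none":
            rpe = update_q(qstate, rec.decision, rec.reward)
            update_weights(
                weights, rpe, rec.decision, rec.phase1_rates,
                dspn_params, ispn_params, C_scale=config.C_scale,
            )
            for (channel, target), w in weights.w.items():
                if channel == rec.decision and w != net.weights[(channel, target)]:
                    net.set_corticostriatal_weight(channel, target, w)
            recorder.record_weights(trial)
        q_rows.append(dict(qstate.q))
        records.append(rec)

    datatables = pd.DataFrame(
        dict(
            trial=[r.trial for r in records],
            decision=[r.decision for r in records],
            correctdecision=[r.correctdecision for r in records],
            reward=[r.reward for r in records],
            decisiontime=[r.decision_time for r in records],
            phase0_ms=[r.phase0_ms for r in records],
            phase1_ms=[r.phase1_ms for r in records],
            phase2_ms=[r.phase2_ms for r in records],
            phase0_peak_drive=[r.phase0_peak_drive for r in records],
            phase1_drive=[r.phase1_drive for r in records],
            decision_rate=[r.decision_rate for r in records],
            opto_applied=[r.opto_applied for r in records],
            stop_applied=[r.stop_applied for r in records],
        )
    )
    recorded: dict[str, pd.DataFrame] = {}
    if "weight" in config.record_variables:
        recorded["weight"] = pd.DataFrame(
            recorder.weight_rows,
            columns=["variable", "time", "trial", "population", "channel", "value"],
        )
    stim_df = pd.DataFrame(
        recorder.stim_rows,
        columns=["variable", "time", "trial", "population", "channel", "value"],
    )
    for name in ("optogenetic_input", "stop_input"):
        if name in config.record_variables:
            recorded[name] = stim_df[stim_df["variable"] == name].reset_index(drop=True)

    bundle = ResultsBundle(config.raw)
    bundle.update(
        seed=seed,
        experimentchoice=config.experimentchoice,
        popfreqs=recorder.popfreqs(),
        datatables=datatables,
        Q_df=pd.DataFrame(q_rows, columns=config.channels),
        recorded_variables=recorded,
        record_variables=list(config.record_variables),
        reward_schedule=pd.DataFrame(schedule.probs, columns=config.channels),
        change_points=list(schedule.change_points),
        final_weights={f"{t}_{c}": w for (c, t), w in weights.w.items()},
        n_neurons=net.n_neurons,
    )
    return bundle
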