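"""Scaled-down synthetic recovery study.

The full-sized pool (26 participants x 140 train / 30 test trials) needs
cluster-scale compute for network training, so the packaged validation
experiment runs the identical pipeline on a reduced pool: 8 participants
(4 healthy at the ceiling score, 4 stroke with scores drawn from the three
chronic-stroke clusters), 60 training and 15 held-out trials each, and the
small CNN configuration (25 conv-1 filters, 2x2 kernels, batch 64, 100
iterations).

Success criteria mirror the clinical yardsticks: held-out single-trial MAE
below 6.6 FMA points (the scale's smallest real difference) and Pearson
r > 0.8 between session-mean predictions and assigned scores.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import evaluate as ev
from .features import LabeledDataset
from .models import CnnConfig, build_model, train_model
from .simulate import SimPoolSpec, SimSpec, simulate_longitudinal, \
    simulate_pool
from .features import assemble_dataset, featurize_recording
from .io import SessionLabel, default_montage

RECOVERY_POOL = SimPoolSpec(n_healthy=4, n_stroke=4, train_trials=60,
                            test_trials=15)
RECOVERY_CONFIG = CnnConfig(conv1_filters=25, conv1_kernel=(2, 2),
                            conv2_filters=25, batch_size=64, iterations=100)


def synthetic_recovery_study(seed: int, pool_spec: SimPoolSpec = RECOVERY_POOL,
                             config: CnnConfig = RECOVERY_CONFIG) -> dict:
    """Simulate, train, and score the reduced pool; returns the key numbers.

    Returns a dict with the trained model and datasets plus: ``trial_mae``
    (held-out single-trial MAE, FMA points), ``session_mae``,
    ``pearson_r`` (session means vs truth) and the per-session table.
    """
    train_set, test_set = simulate_pool(pool_spec, seed=seed)
    trained = train_model(build_model(config), train_set, seed=seed)
    pred = trained.predict(test_set.features)
    trial_mae = float(np.mean(np.abs(pred - test_set.scores)))
    sessions = ev.aggregate_sessions(pred, test_set.index_frame())
    session_pred = [s.predicted for s in sessions]
    session_true = [s.fma_true for s in sessions]
    return {
        "model": trained,
        "train_set": train_set,
        "test_set": test_set,
        "trial_mae": trial_mae,
        "session_mae": ev.mae(sessions),
        "pearson_r": ev.pearson(session_pred, session_true),
        "sessions": sessions,
    }


def longitudinal_study(model, participant_id: str, score: int, seed: int,
                       n_sessions: int = 6, trials_per_session: int = 30,
                       side: str = "right",
                       spec: ev.EquivalenceSpec = ev.EquivalenceSpec()
                       ) -> ev.EquivalenceReport:
    """Within-participant longitudinal check for a trained model.

    Simulates ``n_sessions`` new sessions at a constant score for one
    participant, scores every trial, averages per session, and runs the
    equivalence statistics against the clinical score.
    """
    per_event = 5
    if trials_per_session % per_event:
        raise ValueError("trials_per_session must be a multiple of 5")
    sim = replace(SimSpec(), n_events=trials_per_session // per_event)
    montage = default_montage()
    traj = [(f"s{k + 1}", score) for k in range(n_sessions)]
    recs = simulate_longitudinal(traj, sim, seed=seed, montage=montage,
                                 participant_id=participant_id, side=side)
    parts = []
    for rec in recs:
        values, prov = featurize_recording(rec, montage)
        label = SessionLabel(participant_id, rec.session_id, score, "stroke")
        parts.append(assemble_dataset(values, prov, [label]))
    dataset = LabeledDataset.concatenate(parts)
    return ev.within_participant_eval(model, dataset, spec)
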