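"""Self-adaptive training strategy: monitor-driven learning-rate reduction
and best-model pooling, as a pure state machine over per-epoch metrics.

The controller watches a single scalar per epoch, the monitor

    M = (1 - Accuracy) * Loss

computed from validation accuracy and loss; smaller is better.  It emits
three kinds of actions:

* ``reduce_lr`` — when M has failed to improve on a fixed baseline for
  ``k`` consecutive epochs (an *alert period*), the learning rate is
  multiplied by ``alpha`` (0 < alpha <= 1), bounded below by ``min_lr``.
* ``save_best`` — the model enters the one-slot best-model pool when
  ``M_n <= M_best <= M_threshold`` together with the quality gates
  ``Accuracy >= acc_gate`` and ``Loss <= loss_gate``.  With the default
  gates (0.95, 0.1) the monitor threshold 0.005 = (1 - 0.95) * 0.1 is
  exactly the supremum of monitors that can pass.
* ``reload_best`` — every ``reload_period`` epochs the pooled best
  weights are restored into training.

The controller is framework-agnostic: it exchanges only plain metric
values and actions, never model weights.  ``observe`` is a pure function
of (state, metrics), so any metric stream replays to the identical
action sequence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

__all__ = [
    "ControllerConfig",
    "EpochMetrics",
    "ModelSnapshot",
    "ControllerAction",
    "ControllerState",
    "compute_monitor",
    "init",
    "observe",
    "best_snapshot",
]

SAVE_BEST = "save_best"
REDUCE_LR = "reduce_lr"
RELOAD_BEST = "reload_best"


def compute_monitor(accuracy: float, loss: float) -> float:
    """M = (1 - Accuracy) * Loss; zero iff accuracy is perfect or loss vanishes."""
    if not (0.0 <= accuracy <= 1.0):
        raise ValueError("accuracy must lie in [0, 1]")
    if loss < 0.0:
        raise ValueError("loss must be nonnegative")
    return (1.0 - accuracy) * loss


@dataclass(frozen=True)
class ControllerConfig:
    l0: float = 0.1              # initial learning rate
    alpha: float = 0.5           # reduction factor, 0 < alpha <= 1
    k: int = 5                   # alert-period length in epochs
    m_threshold: float = 0.005   # pool admission threshold on the monitor
    acc_gate: float = 0.95       # pool admission: validation accuracy >= acc_gate
    loss_gate: float = 0.1       # pool admission: validation loss <= loss_gate
    reload_period: int = 10      # epochs between best-model reloads
    min_lr: float = 1e-5

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.l0 <= 0 or self.min_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.m_threshold <= 0 or self.acc_gate <= 0 or self.loss_gate <= 0:
            raise ValueError("thresholds and gates must be positive")
        if self.reload_period < 1:
            raise ValueError("reload_period must be >= 1")


@dataclass(frozen=True)
class EpochMetrics:
    epoch: int
    accuracy: float
    loss: float

    def __post_init__(self):
        if self.epoch < 1:
            raise ValueError("epoch index starts at 1")
        compute_monitor(self.accuracy, self.loss)  # range validation

    @property
    def monitor(self) -> float:
        return compute_monitor(self.accuracy, self.loss)


@dataclass(frozen=True)
class ModelSnapshot:
    """A pool entry: an opaque weights reference plus the metrics at save time."""

    ref: int  # the epoch whose weights are referenced
    metrics: EpochMetrics


@dataclass(frozen=True)
class ControllerAction:
    kind: str
    new_lr: float | None = None
    snapshot: ModelSnapshot | None = None

    def token(self) -> str:
        """Compact form for the curve log's ``actions`` column."""
        if self.kind == REDUCE_LR:
            return f"reduce_lr({self.new_lr:g})"
        if self.kind == SAVE_BEST:
            return "save"
        return "reload"


@dataclass(frozen=True)
class ControllerState:
    config: ControllerConfig
    lr: float
    epoch: int = 0
    alert_active: bool = False
    alert_baseline: float | None = None
    alert_count: int = 0
    m_prev: float | None = None
    m_best: float = field(default=0.005)
    pool: ModelSnapshot | None = None


def init(config: ControllerConfig | None = None) -> ControllerState:
    """Fresh state: lr = l0, no alert, empty pool, M_best = M_threshold.

    Seeding M_best at the threshold makes the chained pool condition
    ``M_n <= M_best <= M_threshold`` satisfiable from an empty pool.
    """
    cfg = config or ControllerConfig()
    return ControllerState(config=cfg, lr=cfg.l0, m_best=cfg.m_threshold)


def observe(
    state: ControllerState, metrics: EpochMetrics
) -> tuple[ControllerState, list[ControllerAction]]:
    """Advance the state machine by one epoch.

    Action order within an epoch is fixed: save_best, reduce_lr,
    reload_best — so an epoch saved at a reload boundary can be reloaded
    immediately.
    """
    cfg = state.config
    if metrics.epoch != state.epoch + 1:
        raise ValueError(
            f"non-consecutive epoch index {metrics.epoch} after {state.epoch}"
        )
    m = metrics.monitor
    actions: list[ControllerAction] = []

    # (a) best-model pool
    m_best, pool = state.m_best, state.pool
    if (
        m <= m_best
        and metrics.accuracy >= cfg.acc_gate
        and metrics.loss <= cfg.loss_gate
    ):
        pool = ModelSnapshot(ref=metrics.epoch, metrics=metrics)
        m_best = m
        actions.append(ControllerAction(SAVE_BEST, snapshot=pool))

    # (b) learning rate: alert-period bookkeeping
    lr = state.lr
    alert, baseline, count = state.alert_active, state.alert_baseline, state.alert_count
    if not alert:
        if state.m_prev is not None and m >= state.m_prev:
            alert, baseline, count = True, state.m_prev, 1
    else:
        if m >= baseline:
            count += 1
        else:  # one sub-baseline epoch cancels the alert
            alert, baseline, count = False, None, 0
    if alert and count >= cfg.k:
        lr = max(lr * cfg.alpha, cfg.min_lr)
        actions.append(ControllerAction(REDUCE_LR, new_lr=lr))
        alert, baseline, count = False, None, 0

    # (c) periodic reload of the pooled best model
    if metrics.epoch % cfg.reload_period == 0 and pool is not None:
        actions.append(ControllerAction(RELOAD_BEST, snapshot=pool))

    new_state = dataclasses.replace(
        state,
        lr=lr,
        epoch=metrics.epoch,
        alert_active=alert,
        alert_baseline=baseline,
        alert_count=count,
        m_prev=m,
        m_best=m_best,
        pool=pool,
    )
    return new_state, actions


def best_snapshot(state: ControllerState) -> ModelSnapshot | None:
    """The pooled best model (minimal monitor, latest on ties), or None."""
    return state.pool
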