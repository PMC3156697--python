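"""Observer pattern: auto-transmit a model whenever its coordinates change.

An :class:`ObservedModel` wraps a mutable model slot; attached observers
each embed a mover and fire it on genuine coordinate changes, subject to a
throttle.  Change detection hashes the serialized coordinate array, so it
is exact over coordinate bits (a 1e-9 move triggers) and insensitive to
renaming: only motion counts.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass

from .client import Mover, TransmissionReport
from .structures import EnergyMap, MolecularModel

__all__ = ["ThrottlePolicy", "Observer", "ObservedModel", "add_observer"]


@dataclass(frozen=True)
class ThrottlePolicy:
    """Gate sends to every Nth coordinate change and a minimum wall interval.

    Both gates must pass.  Counting starts at the first change, so with
    ``every_n_updates = N`` sends happen on changes 1, N+1, 2N+1, ...; the
    first motion is always visible.
    """

    every_n_updates: int = 1
    min_interval_s: float = 0.0

    def __post_init__(self):
        if self.every_n_updates < 1:
            raise ValueError("every_n_updates must be >= 1")
        if self.min_interval_s < 0:
            raise ValueError("min_interval_s must be >= 0")


def _fingerprint(model: MolecularModel) -> bytes:
    return hashlib.sha256(model.coordinates().tobytes()).digest()


class Observer:
    """Watches one container; embeds the mover it fires (exposed as ``.mover``)."""

    def __init__(self, mover: Mover, policy: ThrottlePolicy | None = None, *, clock=time.monotonic):
        self.mover = mover
        self.policy = policy if policy is not None else ThrottlePolicy()
        self._clock = clock
        self._last_fingerprint: bytes | None = None
        self._change_count = 0
        self._last_send_time: float | None = None
        self.sends = 0

    def _on_change(self, model: MolecularModel, energies: EnergyMap | None) -> TransmissionReport | None:
        fp = _fingerprint(model)
        if fp == self._last_fingerprint:
            return None
        self._change_count += 1
        if (self._change_count - 1) % self.policy.every_n_updates != 0:
            self._last_fingerprint = fp
            return None
        now = self._clock()
        if (
            self._last_send_time is not None
            and now - self._last_send_time < self.policy.min_interval_s
        ):
            self._last_fingerprint = fp
            return None
        self._last_fingerprint = fp
        self._last_send_time = now
        self.sends += 1
        return self.mover.apply(model, energies)


class ObservedModel:
    """Mutable model container that notifies attached observers on mutation.

    Mutations go through :meth:`update` (or the ``model`` property setter);
    observers fire only when the coordinate fingerprint actually differs
    from the last one they transmitted.
    """

    def __init__(self, model: MolecularModel):
        self._model = model
        self._observers: list[Observer] = []
        self.update_count = 0  # mutations seen, whether or not coordinates moved
        self.energies: EnergyMap | None = None

    @property
    def model(self) -> MolecularModel:
        return self._model

    @model.setter
    def model(self, new_model: MolecularModel) -> None:
        self.update(new_model)

    def update(self, new_model: MolecularModel, energies: EnergyMap | None = None) -> int:
        """Replace the model and notify observers; returns sends issued (0..n)."""
        self._model = new_model
        if energies is not None:
            self.energies = energies
        self.update_count += 1
        return self.notify_change()

    def notify_change(self) -> int:
        sent = 0
        for obs in self._observers:
            if obs._on_change(self._model, self.energies) is not None:
                sent += 1
        return sent

    def add_observer(self, observer: Observer) -> Observer:
        """Attach; double-attach of the same observer is an idempotent no-op."""
        if observer not in self._observers:
            self._observers.append(observer)
            # Seed the fingerprint so attaching does not itself count as motion.
            observer._last_fingerprint = _fingerprint(self._model)
        return observer

    def remove_observer(self, observer: Observer) -> None:
        if observer in self._observers:
            self._observers.remove(observer)


def add_observer(
    container: ObservedModel, mover: Mover, policy: ThrottlePolicy | None = None
) -> Observer:
    """Attach a new observer embedding *mover* to *container*."""
    return container.add_observer(Observer(mover, policy))
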