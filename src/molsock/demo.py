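"""End-to-end demonstration: stream a perturbation trajectory as a movie.

Generates a synthetic helical backbone, then for each frame perturbs the
coordinates, rescoring with the toy clash score, and lets an observer
transmit the new state.  With ``self_serve`` the datagrams are delivered to
an in-process server recording into a session backend, so the whole
pipeline — serialization, compression, fragmentation, reassembly, dispatch,
coloring — runs without touching real sockets.  A drop-probability shim can
inject loss to demonstrate that incomplete frames are simply never shown.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .client import Link, Mover, Transport, UdpTransport
from .observer import ObservedModel, Observer, ThrottlePolicy
from .render import RecordingBackend
from .server import Server
from .structures import make_synthetic_model, perturb_model, toy_score

__all__ = ["LoopbackTransport", "DemoSummary", "run_demo"]


class LoopbackTransport(Transport):
    """Delivers datagrams straight to a server, optionally dropping some.

    Used by the self-serve demo and by tests; real sockets are untouched.
    """

    def __init__(self, server: Server, drop_probability: float = 0.0, seed: int = 0):
        self.server = server
        self.drop_probability = drop_probability
        self._rng = random.Random(seed)
        self.sent = 0
        self.dropped = 0

    def send(self, datagram: bytes, link: Link) -> bool:
        self.sent += 1
        if self.drop_probability and self._rng.random() < self.drop_probability:
            self.dropped += 1
            return False
        self.server.ingest_datagram(datagram)
        return True


@dataclass
class DemoSummary:
    frames_sent: int = 0
    datagrams_sent: int = 0
    datagrams_dropped: int = 0
    messages_delivered: int = 0
    states_stored: int = 0
    residues_colored: int = 0
    backend: RecordingBackend | None = field(default=None, repr=False)


def run_demo(
    n_frames: int = 10,
    n_residues: int = 50,
    seed: int = 0,
    *,
    endpoints: list[tuple[str, int]] | None = None,
    keep_history: bool = True,
    self_serve: bool = True,
    drop_probability: float = 0.0,
    codec: str = "bz2",
    perturb_magnitude: float = 0.3,
    throttle: ThrottlePolicy | None = None,
) -> DemoSummary:
    """Run the perturbation-movie demonstration; returns a session summary.

    Without ``self_serve`` at least one endpoint must be given (an external
    server is assumed reachable there); with it an in-process server plus
    recording backend receives everything.
    """
    if not self_serve and not endpoints:
        raise ValueError("no endpoints given and self_serve is off")

    backend = None
    server = None
    if self_serve:
        backend = RecordingBackend()
        server = Server(renderer=backend)
        transport: Transport = LoopbackTransport(
            server, drop_probability=drop_probability, seed=seed
        )
    else:
        transport = UdpTransport()

    mover = Mover(
        keep_history=keep_history,
        update_energy=True,
        codec=codec,
        transport=transport,
        scorer=toy_score,
    )
    mover.energy_type = "toy_clash"
    if endpoints:
        mover.set_link(*endpoints[0])
        for host, port in endpoints[1:]:
            mover.add_link(host, port)

    model = make_synthetic_model(n_residues, seed=seed, name="demo_pose")
    container = ObservedModel(model)
    observer = container.add_observer(Observer(mover, throttle))

    summary = DemoSummary(backend=backend)
    for frame in range(n_frames):
        model = perturb_model(model, perturb_magnitude, seed=seed * 100003 + frame + 1)
        container.update(model)
    summary.frames_sent = observer.sends

    if isinstance(transport, LoopbackTransport):
        summary.datagrams_sent = transport.sent
        summary.datagrams_dropped = transport.dropped
    if server is not None:
        summary.messages_delivered = server.messages_delivered
    if backend is not None:
        states = backend.session.states.get("demo_pose", [])
        summary.states_stored = len(states)
        summary.residues_colored = sum(
            1 for c in backend.commands if c.op == "color_residue"
        )
    return summary
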