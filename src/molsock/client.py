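"""Sending side: a mover that streams structures and energies over UDP.

The mover mirrors the viewer-client idiom of molecular-simulation suites:
calling :meth:`Mover.apply` with a model serializes it as PDB text,
compresses it, fragments it into datagrams, and fires them at every
configured endpoint without waiting for any acknowledgement.  Loss is
tolerated by design; an unreachable endpoint never raises.
"""

from __future__ import annotations

import ipaddress
import socket
import uuid as _uuid
from dataclasses import dataclass, field

from . import wire
from .structures import EnergyMap, MolecularModel, serialize_energies, write_pdb

__all__ = [
    "Link",
    "TransmissionReport",
    "Transport",
    "UdpTransport",
    "Mover",
]


@dataclass(frozen=True)
class Link:
    """One UDP endpoint (IPv4 dotted-quad + port)."""

    udp_ip: str = "127.0.0.1"
    udp_port: int = 65000

    def __post_init__(self):
        try:
            ipaddress.IPv4Address(self.udp_ip)
        except ipaddress.AddressValueError:
            raise ValueError(f"invalid IPv4 address {self.udp_ip!r}") from None
        if not 1 <= self.udp_port <= 65535:
            raise ValueError(f"port {self.udp_port} outside 1-65535")

    @property
    def address(self) -> tuple[str, int]:
        return (self.udp_ip, self.udp_port)


class Transport:
    """Abstract datagram sink; exists so tests can inject loss or loopback."""

    def send(self, datagram: bytes, link: Link) -> bool:  # pragma: no cover
        raise NotImplementedError


class UdpTransport(Transport):
    """Fire-and-forget UDP.  Send errors are swallowed: delivery is best-effort."""

    def __init__(self):
        self._sock = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)

    def send(self, datagram: bytes, link: Link) -> bool:
        try:
            self._sock.sendto(datagram, link.address)
            return True
        except OSError:
            return False

    def close(self):
        self._sock.close()


@dataclass
class TransmissionReport:
    """What one send call put on the wire."""

    messages: int = 0
    datagrams_per_link: dict[tuple[str, int], int] = field(default_factory=dict)

    @property
    def total_datagrams(self) -> int:
        return sum(self.datagrams_per_link.values())


class Mover:
    """Streams one model (and optionally its energies) per :meth:`apply`.

    Parameters
    ----------
    keep_history
        When true, transmitted structures carry state flag 1 so the viewer
        appends each as a new state (a movie) instead of replacing the
        current one.
    update_energy, energy_type
        When ``update_energy`` is set, every apply additionally sends the
        ``energy_type`` term (default ``"total"``), either from the
        energies passed to apply or from a configured ``scorer`` callable.
    codec
        Payload compression, ``"bz2"`` (default) or ``"gzip"``.
    """

    def __init__(
        self,
        ip: str = "127.0.0.1",
        port: int = 65000,
        *,
        keep_history: bool = False,
        update_energy: bool = False,
        energy_type: str = "total",
        codec: str = "bz2",
        max_datagram: int = 8192,
        transport: Transport | None = None,
        scorer=None,
    ):
        if codec not in ("bz2", "gzip"):
            raise ValueError(f"codec must be 'bz2' or 'gzip', got {codec!r}")
        self.links: list[Link] = [Link(ip, port)]
        self.keep_history = keep_history
        self.update_energy = update_energy
        self.energy_type = energy_type
        self.codec = codec
        self.max_datagram = max_datagram
        self.scorer = scorer
        self.transport = transport if transport is not None else UdpTransport()
        self.sender_uuid = _uuid.uuid4().bytes
        self._packet_counter = 0  # shared across structure and energy messages

    # -- link management ----------------------------------------------------

    @property
    def link(self) -> Link:
        """The primary endpoint (link 0)."""
        return self.links[0]

    def set_link(self, ip: str, port: int) -> None:
        """Replace the primary endpoint."""
        self.links[0] = Link(ip, port)

    def add_link(self, ip: str, port: int) -> None:
        """Fan out to an additional endpoint; duplicates are idempotent."""
        link = Link(ip, port)
        if link not in self.links:
            self.links.append(link)

    # -- sending ------------------------------------------------------------

    def _next_packet_id(self) -> int:
        pid = self._packet_counter
        self._packet_counter = (self._packet_counter + 1) % (1 << 32)
        return pid

    def _transmit(
        self,
        kind: str,
        payload: bytes,
        model_name: str,
        energy_name: str,
        report: TransmissionReport,
    ) -> None:
        header = wire.PacketHeader(
            sender_uuid=self.sender_uuid,
            packet_id=self._next_packet_id(),
            subpacket_id=0,
            subpacket_total=1,
            payload_type=wire.payload_tag(kind, self.codec),
            state_flag=1 if self.keep_history else 0,
            model_name=model_name.encode("utf-8"),
            energy_name=energy_name.encode("utf-8"),
        )
        compressed = wire.compress_payload(payload, self.codec)
        fragments = wire.fragment_message(header, compressed, self.max_datagram)
        for sp in fragments:
            datagram = wire.encode_subpacket(sp)
            for link in self.links:
                self.transport.send(datagram, link)
                report.datagrams_per_link[link.address] = (
                    report.datagrams_per_link.get(link.address, 0) + 1
                )
        report.messages += 1

    def apply(
        self, model: MolecularModel, energies: EnergyMap | None = None
    ) -> TransmissionReport:
        """Send the model's coordinates (and, if configured, its energies)."""
        report = TransmissionReport()
        self._transmit("structure", write_pdb(model).encode("ascii"), model.name, "", report)
        if self.update_energy:
            if energies is None:
                if self.scorer is None:
                    raise ValueError(
                        "update_energy is set but no energies were supplied "
                        "and no scorer is configured"
                    )
                energies = self.scorer(model)
            self.send_energy(model, energies, self.energy_type, _report=report)
        return report

    def send_energy(
        self,
        model: MolecularModel,
        energies: EnergyMap,
        term: str | None = None,
        *,
        _report: TransmissionReport | None = None,
    ) -> TransmissionReport:
        """Send one per-residue energy table for *term* (default ``"total"``).

        The energies object must carry the requested term: either its own
        term name matches, or the term is ``"total"`` acting as the default
        alias for whatever single term the map holds.
        """
        if term is None:
            term = "total"
        if term not in (energies.term, "total"):
            raise KeyError(
                f"term {term!r} not available (energies carry {energies.term!r})"
            )
        report = _report if _report is not None else TransmissionReport()
        self._transmit(
            "energy", serialize_energies(energies), model.name, term, report
        )
        return report
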