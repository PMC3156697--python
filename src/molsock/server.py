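"""Receiving side: UDP listener, per-sender reassembly, dispatch to a renderer.

The server must survive arbitrary input — a malformed datagram, a corrupt
payload, or a half-delivered message never propagates an exception past the
ingest boundary.  Incomplete messages are held briefly, keyed by
(sender UUID, packet id), and released when they complete, age out, or the
per-sender cap is hit.
"""

from __future__ import annotations

import logging
import socket
import threading
import time
from dataclasses import dataclass, field

from . import wire
from .structures import parse_energies

log = logging.getLogger(__name__)

__all__ = ["ReassemblyBuffer", "Endpoint", "Server", "dispatch"]


@dataclass
class _Partial:
    total: int
    first_seen: float
    header: wire.PacketHeader
    slices: dict[int, bytes] = field(default_factory=dict)


class ReassemblyBuffer:
    """Reassembles fragmented messages from any number of senders.

    Entries are keyed by (sender_uuid, packet_id) — not by source address,
    since a sender may roam ports.  An entry is removed on completion, on
    TTL expiry, or when its sender exceeds the per-sender entry cap
    (oldest evicted first).
    """

    def __init__(self, ttl_s: float = 10.0, per_sender_cap: int = 16):
        self.ttl_s = ttl_s
        self.per_sender_cap = per_sender_cap
        self._entries: dict[tuple[bytes, int], _Partial] = {}
        # recently completed message keys, so late duplicate fragments of an
        # already-delivered message cannot rebuild and re-deliver it
        self._completed: dict[tuple[bytes, int], float] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def ingest(self, raw: bytes, now: float | None = None) -> wire.Message | None:
        """Absorb one datagram; return a Message exactly once, on completion.

        Malformed datagrams are dropped with a warning.  Duplicate
        fragments are idempotent; a conflicting duplicate (same index,
        different bytes) keeps the first copy.  A payload that fails
        decompression discards the whole entry.
        """
        if now is None:
            now = time.monotonic()
        try:
            sp = wire.decode_subpacket(raw)
        except wire.ProtocolError as exc:
            log.warning("dropping malformed datagram (%d bytes): %s", len(raw), exc)
            return None
        h = sp.header
        key = (h.sender_uuid, h.packet_id)
        if key in self._completed:
            return None  # late duplicate of an already-delivered message
        entry = self._entries.get(key)
        if entry is None:
            self._enforce_cap(h.sender_uuid)
            entry = self._entries[key] = _Partial(h.subpacket_total, now, h)
        if h.subpacket_total != entry.total:
            log.warning("fragment with inconsistent total for packet %d; dropped", h.packet_id)
            return None
        if h.subpacket_id in entry.slices:
            if entry.slices[h.subpacket_id] != sp.data:
                log.warning(
                    "conflicting duplicate fragment %d of packet %d; keeping first",
                    h.subpacket_id, h.packet_id,
                )
            return None
        entry.slices[h.subpacket_id] = sp.data
        if len(entry.slices) < entry.total:
            return None
        del self._entries[key]
        self._completed[key] = now
        compressed = b"".join(entry.slices[i] for i in range(entry.total))
        try:
            payload = wire.decompress_payload(compressed, h.payload_type)
        except wire.ProtocolError as exc:
            log.warning("payload validation failed for packet %d: %s", h.packet_id, exc)
            return None
        return wire.Message(
            sender_uuid=h.sender_uuid,
            packet_id=h.packet_id,
            payload_type=h.payload_type,
            state_flag=h.state_flag,
            model_name=entry.header.model_name.decode("utf-8", errors="replace"),
            energy_name=entry.header.energy_name.decode("utf-8", errors="replace"),
            payload=payload,
        )

    def _enforce_cap(self, sender_uuid: bytes) -> None:
        mine = [(k, e) for k, e in self._entries.items() if k[0] == sender_uuid]
        while len(mine) >= self.per_sender_cap:
            oldest = min(mine, key=lambda kv: kv[1].first_seen)
            del self._entries[oldest[0]]
            mine.remove(oldest)
            log.warning("per-sender cap hit; evicted oldest partial message")

    def evict_stale(self, now: float | None = None) -> int:
        """Drop incomplete entries older than the TTL; returns count evicted."""
        if now is None:
            now = time.monotonic()
        stale = [k for k, e in self._entries.items() if now - e.first_seen > self.ttl_s]
        for k in stale:
            del self._entries[k]
        for k in [k for k, t in self._completed.items() if now - t > self.ttl_s]:
            del self._completed[k]
        if stale:
            log.info("evicted %d stale partial message(s)", len(stale))
        return len(stale)


def dispatch(msg: wire.Message, renderer) -> int:
    """Translate one complete message into renderer calls.

    Structure payloads load a model (into the current or next state per the
    message's state flag); energy payloads color residues.  Returns the
    number of render commands issued.  Only these data-bearing operations
    exist — the wire carries no general commands.
    """
    if msg.kind == "structure":
        pdb_text = msg.payload.decode("ascii", errors="replace")
        renderer.load_model(msg.model_name, pdb_text, next_state=msg.state_flag == 1)
        return 1
    try:
        emap = parse_energies(msg.payload, term=msg.energy_name)
    except ValueError as exc:
        log.warning("undecodable energy payload for %s: %s", msg.model_name, exc)
        return 0
    return renderer.color_by_energy(msg.model_name, msg.energy_name, emap)


class Endpoint:
    """One bound UDP socket plus its receive thread."""

    def __init__(self, server: "Server", host: str, port: int):
        self.sock = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)
        try:
            self.sock.bind((host, port))
        except OSError as exc:
            self.sock.close()
            raise OSError(f"cannot bind UDP endpoint {host}:{port}: {exc}") from exc
        self.address = self.sock.getsockname()
        self._server = server
        self._stop = threading.Event()
        self._thread = threading.Thread(target=self._loop, daemon=True)
        self._thread.start()

    def _loop(self):
        self.sock.settimeout(0.1)
        while not self._stop.is_set():
            try:
                raw, _addr = self.sock.recvfrom(65535)
            except socket.timeout:
                continue
            except OSError:
                break
            self._server.ingest_datagram(raw)

    def close(self):
        self._stop.set()
        self._thread.join(timeout=2.0)
        self.sock.close()


class Server:
    """The listener: any number of endpoints feeding one reassembly buffer.

    Complete messages are dispatched to *renderer* (any object with
    ``load_model`` and ``color_by_energy``).  Thread-safe: endpoint threads
    serialize through an internal lock.
    """

    def __init__(self, renderer, *, ttl_s: float = 10.0, per_sender_cap: int = 16):
        self.renderer = renderer
        self.buffer = ReassemblyBuffer(ttl_s=ttl_s, per_sender_cap=per_sender_cap)
        self.endpoints: list[Endpoint] = []
        self.messages_delivered = 0
        self._lock = threading.Lock()

    def start_server(self, host: str = "127.0.0.1", port: int = 65000) -> Endpoint:
        """Bind one more UDP endpoint; call repeatedly to listen on several."""
        ep = Endpoint(self, host, port)
        self.endpoints.append(ep)
        log.info("listening on %s:%d", *ep.address)
        return ep

    def ingest_datagram(self, raw: bytes, now: float | None = None) -> wire.Message | None:
        """Feed one datagram through reassembly and, on completion, dispatch.

        Never raises, whatever the bytes: the sender and receiver must be
        able to run, fail, and restart independently.
        """
        with self._lock:
            try:
                msg = self.buffer.ingest(raw, now=now)
                if msg is not None:
                    self.messages_delivered += 1
                    dispatch(msg, self.renderer)
                self.buffer.evict_stale(now=now)
                return msg
            except Exception:
                log.exception("unexpected error while ingesting datagram")
                return None

    def close(self):
        for ep in self.endpoints:
            ep.close()
        self.endpoints.clear()
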