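"""Listener: reassembly, eviction, robustness, dispatch, real sockets."""

import random
import socket
import time

import pytest

from molsock import wire
from molsock.render import RecordingBackend
from molsock.server import ReassemblyBuffer, Server, dispatch
from molsock.structures import EnergyMap, serialize_energies

UUID_A = bytes(range(16))
UUID_B = bytes(range(16, 32))


INCOMPRESSIBLE = random.Random(0).randbytes(600)


def make_datagrams(payload=INCOMPRESSIBLE, uuid=UUID_A, packet_id=1,
                   kind="structure", codec="bz2", max_datagram=100,
                   model_name=b"m", energy_name=b"", state_flag=0):
    header = wire.PacketHeader(uuid, packet_id, 0, 1, wire.payload_tag(kind, codec),
                               state_flag, model_name, energy_name)
    compressed = wire.compress_payload(payload, codec)
    frags = wire.fragment_message(header, compressed, max_datagram)
    return [wire.encode_subpacket(f) for f in frags], payload


# -- reassembly ------------------------------------------------------------

def test_out_of_order_fragments_deliver_on_last_piece():
    datagrams, payload = make_datagrams()
    assert len(datagrams) >= 3
    buf = ReassemblyBuffer()
    order = [2, 0, 1] + list(range(3, len(datagrams)))
    results = [buf.ingest(datagrams[i], now=0.0) for i in order]
    messages = [m for m in results if m is not None]
    assert len(messages) == 1
    assert messages[0].payload == payload
    assert len(buf) == 0  # entry cleared on completion


def test_duplicate_fragment_never_double_delivers():
    datagrams, payload = make_datagrams()
    buf = ReassemblyBuffer()
    delivered = 0
    for d in datagrams + datagrams:  # every fragment twice
        if buf.ingest(d, now=0.0) is not None:
            delivered += 1
    assert delivered == 1


def test_interleaved_senders_reassemble_independently():
    da, pa = make_datagrams(payload=b"sender A payload " * 30, uuid=UUID_A)
    db, pb = make_datagrams(payload=b"sender B payload " * 40, uuid=UUID_B)
    buf = ReassemblyBuffer()
    messages = []
    for pair in zip(da, db):
        for d in pair:
            m = buf.ingest(d, now=0.0)
            if m:
                messages.append(m)
    for d in (da + db)[len(da):]:  # leftovers of the longer stream
        m = buf.ingest(d, now=0.0)
        if m:
            messages.append(m)
    got = {m.sender_uuid: m.payload for m in messages}
    assert got == {UUID_A: pa, UUID_B: pb}


def test_dropped_fragment_means_no_delivery_and_eventual_eviction():
    datagrams, _ = make_datagrams()
    buf = ReassemblyBuffer(ttl_s=10.0)
    for d in datagrams[:-1]:
        assert buf.ingest(d, now=0.0) is None
    assert len(buf) == 1
    assert buf.evict_stale(now=5.0) == 0   # still within TTL
    assert buf.evict_stale(now=10.01) == 1
    assert len(buf) == 0


def test_per_sender_cap_evicts_oldest_partial():
    buf = ReassemblyBuffer(per_sender_cap=2)
    partials = []
    for pid in range(3):
        ds, _ = make_datagrams(packet_id=pid)
        partials.append(ds)
        buf.ingest(ds[0], now=float(pid))
    assert len(buf) == 2
    # completing the evicted (oldest, pid=0) message must NOT deliver it
    delivered = [buf.ingest(d, now=3.0) for d in partials[0][1:]]
    assert not any(m is not None and m.packet_id == 0 for m in delivered)


def test_corrupt_payload_discards_whole_message():
    datagrams, _ = make_datagrams(max_datagram=8192)
    assert len(datagrams) == 1
    hlen = wire.decode_header(datagrams[0])[1]
    corrupted = bytearray(datagrams[0])
    corrupted[hlen + 5] ^= 0xFF
    buf = ReassemblyBuffer()
    assert buf.ingest(bytes(corrupted), now=0.0) is None
    assert len(buf) == 0


def test_random_bytes_never_raise():
    rng = random.Random(42)
    buf = ReassemblyBuffer()
    for _ in range(2000):
        blob = rng.randbytes(rng.randrange(0, 200))
        assert buf.ingest(blob, now=0.0) is None


def test_delivery_count_equals_completed_messages_under_reorder_and_dupes():
    rng = random.Random(7)
    buf = ReassemblyBuffer()
    delivered = 0
    expected = 0
    for pid in range(20):
        ds, _ = make_datagrams(packet_id=pid, payload=rng.randbytes(rng.randrange(1, 800)))
        stream = ds + [rng.choice(ds) for _ in range(3)]  # duplicates
        rng.shuffle(stream)
        expected += 1
        for d in stream:
            if buf.ingest(d, now=0.0) is not None:
                delivered += 1
    assert delivered == expected
    assert len(buf) == 0


# -- dispatch --------------------------------------------------------------

def test_structure_then_energy_dispatch(helix10):
    from molsock import toy_score, write_pdb

    backend = RecordingBackend()
    pdb_msg = wire.Message(UUID_A, 0, "PDB.bz2", 0, helix10.name, "",
                           write_pdb(helix10).encode())
    assert dispatch(pdb_msg, backend) == 1
    emap = toy_score(helix10)
    ene_msg = wire.Message(UUID_A, 1, "Ener.bz2", 0, helix10.name, "toy_clash",
                           serialize_energies(emap))
    assert dispatch(ene_msg, backend) == len(emap.values)


def test_energy_for_unknown_model_warns_not_crashes(caplog):
    backend = RecordingBackend()
    msg = wire.Message(UUID_A, 0, "Ener.bz2", 0, "ghost", "total",
                       serialize_energies(EnergyMap("total", {("A", 1): 1.0})))
    assert dispatch(msg, backend) == 0


def test_history_messages_stack_into_successive_states(helix10):
    from molsock import perturb_model, write_pdb

    backend = RecordingBackend()
    server = Server(backend)
    for k in range(3):
        m = perturb_model(helix10, 0.2, seed=k + 1)
        datagrams, _ = make_datagrams(payload=write_pdb(m).encode(),
                                      packet_id=k, state_flag=1,
                                      model_name=helix10.name.encode(),
                                      max_datagram=8192)
        for d in datagrams:
            server.ingest_datagram(d, now=0.0)
    assert len(backend.session.states[helix10.name]) == 3


# -- real sockets ----------------------------------------------------------

def wait_for(predicate, timeout=5.0):
    deadline = time.monotonic() + timeout
    while time.monotonic() < deadline:
        if predicate():
            return True
        time.sleep(0.02)
    return predicate()


def test_server_listens_on_multiple_endpoints(helix10):
    from molsock import Mover, write_pdb

    backend = RecordingBackend()
    server = Server(backend)
    try:
        ep1 = server.start_server("127.0.0.1", 0)
        ep2 = server.start_server("127.0.0.1", 0)
        assert ep1.address[1] != ep2.address[1]
        # two independent senders, one per endpoint (distinct UUIDs)
        Mover(*ep1.address).apply(helix10)
        Mover(*ep2.address).apply(helix10)
        assert wait_for(lambda: server.messages_delivered >= 2)
        [stored] = backend.session.states[helix10.name]
        assert write_pdb(stored) == write_pdb(helix10)
    finally:
        server.close()


def test_duplicate_bind_is_an_endpoint_error():
    server = Server(RecordingBackend())
    try:
        ep = server.start_server("127.0.0.1", 0)
        with pytest.raises(OSError, match="cannot bind"):
            # bind the very same port again outside SO_REUSEADDR
            server.start_server("127.0.0.1", ep.address[1])
    finally:
        server.close()
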