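# molsock

Real-time, loss-tolerant streaming of protein structures and per-residue
energies from a simulation process to a visualization process, over UDP.

Structure-prediction and design calculations are far easier to understand
when you can watch them: every accepted move, every score change, as it
happens. molsock implements the transport that makes this possible while
keeping the simulation and the viewer fully decoupled — they run as
separate processes (even on separate machines and operating systems), and
either can start, stop, or crash without affecting the other.

**Who it is for:** anyone instrumenting an iterative molecular calculation
(Monte Carlo, minimization, docking) who wants live visual output — or a
recorded, replayable movie of a trajectory — without linking a viewer into
the simulation process.

## How it works

A **mover** is attached to the simulation side. Each time it is applied to
a model it serializes the conformation as PDB text, compresses it (bz2 or
gzip), splits it into datagram-sized **sub-packets** — each carrying a full
metadata header (sender UUID, packet id, fragment index/count, payload
type, state flag, model and energy names) — and fires them at one or more
UDP endpoints. No handshake, no retransmission: a lost frame is simply
never shown.

An **observer** wraps a mover and watches a model container, transmitting
automatically whenever coordinates actually change, with optional
throttling (every Nth change and/or a minimum time interval).

The **server** listens on any number of endpoints, reassembles fragments
per sender, validates each payload by decompression, and dispatches
complete messages to a render backend: structures load into viewer states
(with `keep_history`, successive transmissions stack into a movie), and
energy tables color residues on a spectrum from blue (lowest value in the
map, most favorable) through green to red (highest, least favorable),
normalized per message:

    t = (value - vmin) / (vmax - vmin),  hue = 240° * (1 - t)   (HSV, S=V=1)

The byte-level wire contract, with hex test vectors, is in
[docs/PROTOCOL.md](docs/PROTOCOL.md); the modeling choices are in
[docs/methods.md](docs/methods.md).

## Worked example

Stream a ten-frame perturbation movie of a 50-residue synthetic helix
through an in-process server and record the session:

```sh
$ molsock demo --frames 10 --residues 50 --seed 1 --session-out session.pml
frames sent: 10  datagrams: 20 (dropped 0)  messages delivered: 20  states stored: 10  residues colored: 500
session script written to session.pml
```

Each frame produced two messages (coordinates + toy clash-score energies),
all 20 arrived, the ten structure messages stacked into ten viewer states
(a movie), and each of the ten energy messages colored all 50 residues.
`session.pml` is a replayable viewer command script.

The same pipeline from the library:

```python
from molsock import Mover, Server, RecordingBackend, make_synthetic_model, toy_score

backend = RecordingBackend()
server = Server(backend)
endpoint = server.start_server("127.0.0.1", 0)       # ephemeral port

pose = make_synthetic_model(50, seed=1, name="pose")
mover = Mover(*endpoint.address, keep_history=True, update_energy=True, scorer=toy_score)
mover.energy_type = "toy_clash"
mover.apply(pose)                                     # structure + energies, over real UDP
```

`molsock serve` runs a standalone listener and `molsock send` transmits a
PDB file from the shell; an observer (`molsock.add_observer`) automates
transmission inside a simulation loop.

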