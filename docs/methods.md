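# Methods

## What the package models

molsock streams molecular conformations and per-residue scalar energies
from a running simulation process to a separate visualization process over
UDP. The design premise is that visualization is advisory: a dropped frame
costs nothing, so the transport is fire-and-forget — no handshake, no
acknowledgement, no retransmission — and the two processes can start, stop,
or crash independently. What UDP does *not* give for free is integrity and
size: datagrams are bounded, so payloads are compressed and fragmented, and
delivery is unreliable, so a message acts only when every fragment has
arrived and the payload decompresses cleanly. The full byte-level contract
is in `docs/PROTOCOL.md`.

The sending side follows the mover/observer idiom of molecular simulation
frameworks: a **mover** transmits the current pose when applied; an
**observer** wraps a mover and fires it automatically whenever the watched
model's coordinates actually change. The receiving side is a listener that
reassembles messages per sender and dispatches them to a render backend,
either loading a structure into a viewer state or coloring residues by
energy.

## Parameters that matter

| Parameter | Default | Units | Why |
|---|---|---|---|
| `max_datagram` | 8192 | bytes | safely below common UDP limits while keeping a typical compressed structure in a handful of fragments |
| `codec` | bz2 | — | better ratio on PDB text; gzip available for speed |
| `ttl_s` | 10 | s | incomplete messages are held "briefly": long enough to ride out reordering, short enough to bound memory |
| `per_sender_cap` | 16 | entries | bounds memory per sender under sustained loss |
| `keep_history` | off | — | on: each transmission appends a viewer state (movie); off: replaces the current state |
| `every_n_updates`, `min_interval_s` | 1, 0 | —, s | observer throttle; both gates must pass |

Integer byte order is big-endian so datagrams read identically across
platforms. gzip compression pins `mtime=0` so identical payloads produce
identical datagrams, which makes recorded sessions reproducible
byte-for-byte.

## Change detection and throttling

The observer fingerprints the serialized coordinate array (SHA-256 of the
float64 buffer in atom order). Detection is therefore exact over coordinate
bits — a 1e-9 Å move triggers, renaming does not — and order-sensitive over
atoms. The fingerprint is compared against the last *seen* state, so every
genuine mutation counts toward the every-Nth gate even while throttled;
counting starts at the first change (sends on changes 1, N+1, 2N+1, ...) so
the first motion is always visible. The wall-clock gate compares against
the last *sent* time. These semantics are this package's own definition;
the throttle's two knobs (count interval, time interval) are the behavior a
user needs to keep packet construction from slowing a simulation.

## Energy coloring

Energy payloads carry raw per-residue scalars, never colors: the wire
format stays renderer-agnostic and the receiver owns the palette. Coloring
normalizes per message — vmin/vmax are the incoming map's own extrema — so
what is shown is always the *relative* energy distribution of the current
frame. The spectrum sweeps HSV hue linearly from 240° (blue, minimum /
most favorable) to 0° (red, maximum / least favorable) at full saturation
and value; the midpoint is green, and a degenerate map (all values equal)
maps everything to mid-spectrum green. An HSV sweep rather than a naive RGB
interpolation reproduces the rainbow appearance of standard spectrum
coloring. Endpoint colors are fixed by convention; interior hues are this
package's choice.

## Reassembly policy

Partial messages are keyed by `(sender UUID, packet id)` and never by
source address, since a sender may roam ports behind NAT or reconnects.
Delivery is exactly-once: completed keys are remembered for one TTL so a
late duplicate fragment cannot rebuild and re-deliver a message.
"Abort" of a partial message is defined here as TTL expiry or cap
eviction — nothing else discards a partial. Only two data-bearing
operations exist (load structure, color by energy); the server never
executes general commands from the wire, which is the whole of its
security model.

## Synthetic data

`make_synthetic_model` builds a poly-alanine-like backbone (N, CA, C, O per
residue) on an ideal helical curve with 1.5 Å rise and 100° twist per
residue; the CA radius (2.28 Å) is chosen so consecutive CA–CA distances
come out near the peptide-like 3.8 Å. The seed adds only a ≤0.05 Å jitter,
so different seeds give distinct but equally plausible conformations.
`perturb_model` adds bounded uniform coordinate noise (demo default 0.3 Å
per frame — visible motion without tearing the backbone), and `toy_score`
counts, per residue, atoms of other residues within 3.0 Å (a clash count).

What this emulates: the *plumbing* of a structure-prediction run — a pose
that moves every iteration and a score that varies along the chain. What it
does not emulate: real chemistry (side chains, realistic force fields,
score magnitudes), large structures (megadalton complexes would fragment
into many more datagrams), or real network pathology (WAN reordering,
fragmentation at the IP layer, MTU discovery). Passing tests therefore
demonstrate protocol correctness and pipeline integrity, not biological
realism or WAN-scale performance.

## Numerical and design choices

- PDB coordinates are written to 3 decimals, so the structure round trip
  is exact to 0.001 Å by construction; the synthetic generator rounds its
  coordinates to the same precision so round trips are bit-exact.
- Energy values serialize via `repr`, so the energy round trip is exact to
  the bit for any finite float64.
- 1-based residue numbering, no insertion codes, single-character chains;
  occupancy/B-factor fixed at 1.00/0.00. ANISOU/MODEL/altloc records are
  out of scope for the wire payload (multi-state PDB with MODEL blocks is
  used only in session export).
- A mover supports multiple links (fan-out to several endpoints) in
  addition to the one-mover-per-endpoint pattern; the wire behavior is
  identical, fan-out just duplicates datagrams.
- Structure is sent before energy when both go out in one apply, since
  coloring needs the model present at the receiver.
- The toy clash score uses a k-d tree for neighbor search; the tests check
  it against an exhaustive all-pairs computation.
- Problem sizes in the test and acceptance runs (100-residue models,
  500-case fragmentation sweeps, 10 000-datagram fuzz, 10-frame movies)
  were chosen to exercise every code path — multi-fragment payloads, both
  codecs, loss, reordering — while keeping the default suite fast.

## Known limitations

- IPv4 only; IPv6 is future work.
- No authentication or rate limiting: the listener trusts its network.
- Change detection offers no tolerance band; simulations that jitter
  coordinates at machine precision will transmit every step (use the
  throttle).
- Per-message color normalization means colors are not comparable across
  frames; a fixed-range mode would be needed for that.
- The loopback demo exercises loss via an in-process shim; real-socket
  tests run only on the local loopback interface.
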