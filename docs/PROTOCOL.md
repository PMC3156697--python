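# molsock wire protocol

Transport is UDP/IP, fire-and-forget: no handshake, no acknowledgement, no
retransmission. Either side can start, stop, or crash without affecting the
other; because delivery is unreliable, every reassembled payload is
validated (it must decompress cleanly) before any action is taken.

## Datagram layout

Every datagram is one **sub-packet**: a full metadata header followed by a
contiguous slice of the compressed payload. All integers are unsigned
big-endian (network order), so datagrams are interpreted identically across
platforms.

| Bytes | Field |
|------:|-------|
| 16    | Sender UUID, random per client instance |
| 4     | Packet id, unique per sender per message (wrapping counter) |
| 4     | Sub-packet id, 0-based |
| 4     | Total number of sub-packets (>= 1) |
| 8     | Payload type tag, ASCII, right-padded with spaces |
| 1     | State flag: 0 = replace the current viewer state, 1 = append as the next state |
| 1 + N | Model name length + model name (N <= 255) |
| 1 + N | Energy name length + energy name (empty for structure payloads) |
| X     | Compressed payload slice |

The fixed part is 37 bytes; the minimum header (both names empty) is 39.

### Payload type tags

| Tag        | Payload        | Codec |
|------------|----------------|-------|
| `PDB.bz2 ` | PDB text       | bz2   |
| `PDB.gzip` | PDB text       | gzip  |
| `Ener.bz2` | energy table   | bz2   |
| `Ene.gzip` | energy table   | gzip  |

The tag stems for energy payloads are historically inconsistent
(`Ener` for bz2, `Ene` for gzip). Encoders emit exactly the four tags
above; decoders additionally accept `Ene.bz2 `. `Ener.gzip` would be nine
bytes and therefore cannot occur in the 8-byte field.

## Fragmentation and reassembly

A message's compressed payload is sliced into
`ceil(payload_len / (max_datagram - header_len))` sub-packets (at least
one, even for an empty payload), each carrying the **full** header with its
own sub-packet id. Default `max_datagram` is 8192 bytes. Receivers key
partial messages by `(sender UUID, packet id)` — never by source address —
and deliver a message exactly once, when all slices are present and the
payload decompresses. Incomplete entries are evicted after a TTL
(default 10 s) or when a sender exceeds its partial-entry cap (default 16,
oldest first). A duplicate fragment is a no-op; a conflicting duplicate
(same id, different bytes) keeps the first copy.

## Payload dialects

**Structure** payloads are PDB v3.3 text: fixed-column `ATOM` records
(coordinates to 3 decimals, occupancy 1.00, B-factor 0.00, element
right-justified), one `TER` per chain, `END` last.

**Energy** payloads are ASCII lines

    <chain_id> <residue_number> <value>\n

with values in repr-faithful decimal so the round trip is exact. The score
term name travels in the header's energy-name field, not in the payload.

## Test vectors

Header with model name `pose`, no energy name, packet id 1, single
fragment, state flag 1, tag `PDB.bz2`:

```
00010203 04050607 08090a0b 0c0d0e0f   sender UUID
00000001                              packet id
00000000                              sub-packet id
00000001                              sub-packet total
5044422e 627a3220                     "PDB.bz2 "
01                                    state flag
04 706f7365                           len + "pose"
00                                    len + "" (energy name)
```

43 bytes total. A second vector with both names appears in
`tests/test_acceptance.py`.

## Viewer-script dialect

Recorded sessions export as a rigid PyMOL-style command script, one
instruction per render command:

```
cmd.read_pdbstr("""<pdb text>__END_PDB__""", "<name>", state=<k>)
cmd.set_color("molsock_<chain>_<resnum>", [<r>, <g>, <b>])   # 0-1, 3 decimals
cmd.color("molsock_<chain>_<resnum>", "<name> and chain <chain> and resi <resnum>")
```

The `__END_PDB__` sentinel makes the script machine-invertible;
`molsock.render.parse_viewer_script` reads it back losslessly.
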