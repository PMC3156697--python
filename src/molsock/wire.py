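"""Datagram wire format: header codec, payload compression, fragmentation.

Every UDP datagram carries a fixed-layout metadata header followed by a
slice of the (bz2- or gzip-) compressed payload.  Large payloads are split
into sub-packets, each repeating the full header with its own sub-packet
index, so a receiver can reassemble them statelessly and in any order.

Layout, in wire order (integers big-endian):

====  =========================================================
 16   sender UUID (raw bytes, random per client instance)
  4   packet id, unique per sender per message
  4   sub-packet id (0-based)
  4   total number of sub-packets
  8   payload type tag, space-padded ASCII
  1   state flag: 0 = replace current state, 1 = append next state
 1+N  model name length + model name
 1+N  energy name length + energy name
  X   compressed payload slice
====  =========================================================
"""

from __future__ import annotations

import bz2
import gzip
import struct
import zlib
from dataclasses import dataclass, replace

__all__ = [
    "ProtocolError",
    "MalformedPacketError",
    "PayloadTypeError",
    "NameLengthError",
    "FragmentationError",
    "PayloadValidationError",
    "PacketHeader",
    "SubPacket",
    "Message",
    "FIXED_HEADER_LEN",
    "MIN_HEADER_LEN",
    "TAG_WIDTH",
    "PAYLOAD_TAGS",
    "payload_tag",
    "tag_codec",
    "tag_kind",
    "encode_header",
    "decode_header",
    "compress_payload",
    "decompress_payload",
    "fragment_message",
    "encode_subpacket",
    "decode_subpacket",
]


class ProtocolError(ValueError):
    """Base class for wire-format violations."""


class MalformedPacketError(ProtocolError):
    """Datagram bytes do not parse as a valid sub-packet."""


class PayloadTypeError(ProtocolError):
    """Unknown payload-type tag."""


class NameLengthError(ProtocolError):
    """Model or energy name exceeds the 255-byte length prefix."""


class FragmentationError(ProtocolError):
    """Datagram budget too small to carry the header plus any data."""


class PayloadValidationError(ProtocolError):
    """Reassembled payload failed decompression; the message is dropped."""


#: fixed-width fields: uuid(16) + packet_id(4) + sub_id(4) + total(4) + tag(8) + flag(1)
FIXED_HEADER_LEN = 37
#: minimum encoded header: fixed part plus two zero length bytes
MIN_HEADER_LEN = FIXED_HEADER_LEN + 2
TAG_WIDTH = 8

#: canonical tags, as emitted on the wire (before space padding)
PAYLOAD_TAGS = ("PDB.bz2", "Ener.bz2", "PDB.gzip", "Ene.gzip")

# The historical tag set uses inconsistent stems for energy payloads
# ("Ener.bz2" but "Ene.gzip"); the short stem is also accepted for bz2.
# ("Ener.gzip" would be 9 bytes and cannot exist in the 8-byte tag field.)
_DECODE_TAGS = frozenset(PAYLOAD_TAGS) | {"Ene.bz2"}

_FIXED_STRUCT = struct.Struct(">16sIII8sB")


def payload_tag(kind: str, codec: str) -> str:
    """Canonical tag for a payload *kind* ('structure'|'energy') and codec."""
    try:
        return {
            ("structure", "bz2"): "PDB.bz2",
            ("structure", "gzip"): "PDB.gzip",
            ("energy", "bz2"): "Ener.bz2",
            ("energy", "gzip"): "Ene.gzip",
        }[(kind, codec)]
    except KeyError:
        raise PayloadTypeError(f"no tag for kind={kind!r} codec={codec!r}") from None


def tag_codec(tag: str) -> str:
    """Codec named by a tag's suffix: '.bz2' -> bz2, '.gzip' -> gzip."""
    if tag.endswith(".bz2"):
        return "bz2"
    if tag.endswith(".gzip"):
        return "gzip"
    raise PayloadTypeError(f"tag {tag!r} names no known codec")


def tag_kind(tag: str) -> str:
    """Payload kind named by a tag's stem: 'structure' or 'energy'."""
    stem = tag.split(".", 1)[0]
    if stem == "PDB":
        return "structure"
    if stem in ("Ene", "Ener"):
        return "energy"
    raise PayloadTypeError(f"tag {tag!r} names no known payload kind")


@dataclass(frozen=True)
class PacketHeader:
    """Metadata preceding every datagram's data block."""

    sender_uuid: bytes
    packet_id: int
    subpacket_id: int
    subpacket_total: int
    payload_type: str
    state_flag: int
    model_name: bytes = b""
    energy_name: bytes = b""

    def validate(self) -> None:
        if len(self.sender_uuid) != 16:
            raise MalformedPacketError("sender_uuid must be exactly 16 bytes")
        for field in ("packet_id", "subpacket_id", "subpacket_total"):
            v = getattr(self, field)
            if not 0 <= v <= 0xFFFFFFFF:
                raise MalformedPacketError(f"{field}={v} outside unsigned 32-bit range")
        if self.subpacket_total < 1:
            raise MalformedPacketError("subpacket_total must be >= 1")
        if self.subpacket_id >= self.subpacket_total:
            raise MalformedPacketError(
                f"subpacket_id {self.subpacket_id} >= total {self.subpacket_total}"
            )
        if self.payload_type not in _DECODE_TAGS:
            raise PayloadTypeError(f"unknown payload type {self.payload_type!r}")
        if self.state_flag not in (0, 1):
            raise MalformedPacketError(f"state_flag must be 0 or 1, got {self.state_flag}")
        for label, name in (("model", self.model_name), ("energy", self.energy_name)):
            if len(name) > 255:
                raise NameLengthError(f"{label} name is {len(name)} bytes (limit 255)")

    @property
    def encoded_length(self) -> int:
        return FIXED_HEADER_LEN + 1 + len(self.model_name) + 1 + len(self.energy_name)


@dataclass(frozen=True)
class SubPacket:
    """One datagram: a full header plus a contiguous slice of the payload."""

    header: PacketHeader
    data: bytes


@dataclass(frozen=True)
class Message:
    """A fully reassembled, decompressed transmission."""

    sender_uuid: bytes
    packet_id: int
    payload_type: str
    state_flag: int
    model_name: str
    energy_name: str
    payload: bytes

    @property
    def kind(self) -> str:
        return tag_kind(self.payload_type)


def encode_header(h: PacketHeader) -> bytes:
    """Serialize a header in wire order.  Raises on any invalid field."""
    h.validate()
    tag = h.payload_type.ljust(TAG_WIDTH).encode("ascii")
    fixed = _FIXED_STRUCT.pack(
        h.sender_uuid, h.packet_id, h.subpacket_id, h.subpacket_total, tag, h.state_flag
    )
    return (
        fixed
        + bytes([len(h.model_name)])
        + h.model_name
        + bytes([len(h.energy_name)])
        + h.energy_name
    )


def decode_header(b: bytes) -> tuple[PacketHeader, int]:
    """Parse a header from the front of a datagram.

    Returns the header and its encoded byte length so the caller can slice
    off the data block.  Any structural problem raises
    :class:`MalformedPacketError` (or a subclass); the server drops such
    datagrams rather than crash.
    """
    if len(b) < MIN_HEADER_LEN:
        raise MalformedPacketError(
            f"datagram of {len(b)} bytes is shorter than the {MIN_HEADER_LEN}-byte minimum header"
        )
    uid, pid, sid, total, raw_tag, flag = _FIXED_STRUCT.unpack_from(b, 0)
    try:
        tag = raw_tag.decode("ascii").rstrip(" ")
    except UnicodeDecodeError:
        raise MalformedPacketError(f"payload tag {raw_tag!r} is not ASCII") from None
    pos = FIXED_HEADER_LEN
    names = []
    for label in ("model", "energy"):
        if pos >= len(b):
            raise MalformedPacketError(f"truncated before {label}-name length byte")
        n = b[pos]
        pos += 1
        if pos + n > len(b):
            raise MalformedPacketError(f"truncated {label} name ({n} bytes declared)")
        names.append(bytes(b[pos : pos + n]))
        pos += n
    header = PacketHeader(uid, pid, sid, total, tag, flag, names[0], names[1])
    header.validate()
    return header, pos


def compress_payload(raw: bytes, codec: str) -> bytes:
    """Compress a payload with bz2 or gzip (deterministic output)."""
    if codec == "bz2":
        return bz2.compress(raw)
    if codec == "gzip":
        return gzip.compress(raw, mtime=0)
    raise PayloadTypeError(f"unknown codec {codec!r}")


def decompress_payload(data: bytes, payload_type: str) -> bytes:
    """Decompress a reassembled payload; the tag suffix selects the codec.

    A payload that fails to decompress raises
    :class:`PayloadValidationError` — this is the delivery-validation step
    that an unreliable transport requires, and the caller drops the message.
    """
    codec = tag_codec(payload_type)
    try:
        if codec == "bz2":
            return bz2.decompress(data)
        return gzip.decompress(data)
    except (OSError, ValueError, EOFError, zlib.error) as exc:
        raise PayloadValidationError(f"payload failed {codec} decompression: {exc}") from exc


def fragment_message(
    header: PacketHeader, compressed_payload: bytes, max_datagram: int = 8192
) -> list[SubPacket]:
    """Split a compressed payload into datagram-sized sub-packets.

    Every sub-packet repeats the full header (names included) with its own
    ``subpacket_id``; the data slices concatenate, in index order, back to
    the payload.  ``max_datagram`` bounds the encoded datagram size, so the
    per-fragment data capacity is ``max_datagram - header_length``.
    """
    header.validate()
    capacity = max_datagram - header.encoded_length
    if capacity <= 0:
        raise FragmentationError(
            f"{header.encoded_length}-byte header leaves no room in a "
            f"{max_datagram}-byte datagram"
        )
    n = max(1, -(-len(compressed_payload) // capacity))  # ceil; empty payload -> 1
    out = []
    for i in range(n):
        h = replace(header, subpacket_id=i, subpacket_total=n)
        out.append(SubPacket(h, compressed_payload[i * capacity : (i + 1) * capacity]))
    return out


def encode_subpacket(sp: SubPacket) -> bytes:
    return encode_header(sp.header) + sp.data


def decode_subpacket(b: bytes) -> SubPacket:
    header, hlen = decode_header(b)
    return SubPacket(header, bytes(b[hlen:]))
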