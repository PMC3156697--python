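"""YAML configuration for endpoints, codec, reassembly, and throttling."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import yaml

from .client import Link
from .observer import ThrottlePolicy

log = logging.getLogger(__name__)

__all__ = ["AppConfig", "load_config", "dump_config"]

_KNOWN_KEYS = {"endpoints", "codec", "ttl_s", "per_sender_cap", "every_n_updates", "min_interval_s", "max_datagram", "keep_history"}


@dataclass
class AppConfig:
    endpoints: list[Link] = field(default_factory=lambda: [Link()])
    codec: str = "bz2"
    ttl_s: float = 10.0
    per_sender_cap: int = 16
    max_datagram: int = 8192
    keep_history: bool = False
    throttle: ThrottlePolicy = field(default_factory=ThrottlePolicy)


def load_config(path) -> AppConfig:
    """Read a YAML config; missing keys default, unknown keys warn.

    Raises ``ValueError`` on invalid values (bad port, unknown codec, ...).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    for key in set(raw) - _KNOWN_KEYS:
        log.warning("unknown config key %r ignored", key)
    cfg = AppConfig()
    if "endpoints" in raw:
        eps = raw["endpoints"]
        if not isinstance(eps, list) or not eps:
            raise ValueError("endpoints must be a non-empty list")
        cfg.endpoints = [Link(str(e["host"]), int(e["port"])) for e in eps]
    if "codec" in raw:
        if raw["codec"] not in ("bz2", "gzip"):
            raise ValueError(f"codec must be bz2 or gzip, got {raw['codec']!r}")
        cfg.codec = raw["codec"]
    if "ttl_s" in raw:
        cfg.ttl_s = float(raw["ttl_s"])
        if cfg.ttl_s <= 0:
            raise ValueError("ttl_s must be positive")
    if "per_sender_cap" in raw:
        cfg.per_sender_cap = int(raw["per_sender_cap"])
        if cfg.per_sender_cap < 1:
            raise ValueError("per_sender_cap must be >= 1")
    if "max_datagram" in raw:
        cfg.max_datagram = int(raw["max_datagram"])
        if cfg.max_datagram < 64:
            raise ValueError("max_datagram unreasonably small")
    if "keep_history" in raw:
        cfg.keep_history = bool(raw["keep_history"])
    cfg.throttle = ThrottlePolicy(
        every_n_updates=int(raw.get("every_n_updates", 1)),
        min_interval_s=float(raw.get("min_interval_s", 0.0)),
    )
    return cfg


def dump_config(cfg: AppConfig) -> str:
    """Serialize a config back to YAML (inverse of :func:`load_config`)."""
    return yaml.safe_dump(
        {
            "endpoints": [{"host": l.udp_ip, "port": l.udp_port} for l in cfg.endpoints],
            "codec": cfg.codec,
            "ttl_s": cfg.ttl_s,
            "per_sender_cap": cfg.per_sender_cap,
            "max_datagram": cfg.max_datagram,
            "keep_history": cfg.keep_history,
            "every_n_updates": cfg.throttle.every_n_updates,
            "min_interval_s": cfg.throttle.min_interval_s,
        },
        sort_keys=True,
    )
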