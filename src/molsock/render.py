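"""Display contract: render commands, a recording backend, spectrum coloring.

The server never talks to a real viewer directly; it issues backend-neutral
:class:`RenderCommand` objects.  The :class:`RecordingBackend` stores them
as a replayable session (the test oracle and the session store), and
:func:`to_viewer_script` emits an equivalent PyMOL-dialect command script
that :func:`parse_viewer_script` can read back losslessly.

Energy coloring follows the molecular-viewer spectrum convention: blue for
the lowest (most favorable) value through the rainbow to red for the
highest, normalized per message over the map's own min/max.
"""

from __future__ import annotations

import colorsys
import logging
import math
import re
from dataclasses import dataclass, field

from .structures import EnergyMap, MolecularModel, parse_pdb, write_pdb

log = logging.getLogger(__name__)

__all__ = [
    "RenderCommand",
    "SessionState",
    "RecordingBackend",
    "spectrum_color",
    "to_viewer_script",
    "parse_viewer_script",
    "replay",
]


def spectrum_color(value: float, vmin: float, vmax: float) -> tuple[int, int, int]:
    """Map a scalar onto the blue->red energy spectrum.

    The position ``t = (value - vmin) / (vmax - vmin)`` (clamped to [0, 1])
    selects an HSV hue swept linearly from 240 deg (blue, low/favorable)
    down to 0 deg (red, high/unfavorable), at full saturation and value.
    A degenerate range (vmin == vmax) maps to mid-spectrum green.
    """
    if not math.isfinite(value):
        raise ValueError(f"non-finite energy value {value!r}")
    if vmin > vmax:
        raise ValueError(f"vmin {vmin} > vmax {vmax}")
    if vmin == vmax:
        t = 0.5
    else:
        t = min(1.0, max(0.0, (value - vmin) / (vmax - vmin)))
    hue = 240.0 * (1.0 - t)
    r, g, b = colorsys.hsv_to_rgb(hue / 360.0, 1.0, 1.0)
    return (round(r * 255), round(g * 255), round(b * 255))


@dataclass(frozen=True)
class RenderCommand:
    """One backend-neutral display instruction."""

    op: str  # "load_model" | "color_residue"
    #: load_model: (name, state, pdb_text); color_residue: (name, chain, resnum, (r, g, b))
    args: tuple

    def __post_init__(self):
        if self.op == "load_model":
            _, state, _ = self.args
            if state < 1:
                raise ValueError("state index must be >= 1")
        elif self.op == "color_residue":
            rgb = self.args[3]
            if any(not 0 <= c <= 255 for c in rgb):
                raise ValueError(f"rgb components {rgb} outside 0-255")
        else:
            raise ValueError(f"unknown render op {self.op!r}")


@dataclass
class SessionState:
    """Per-model-name movie states and current residue colors."""

    states: dict[str, list[MolecularModel]] = field(default_factory=dict)
    colors: dict[str, dict[tuple[str, int], tuple[int, int, int]]] = field(default_factory=dict)

    def __eq__(self, other):
        if not isinstance(other, SessionState):
            return NotImplemented
        return self.colors == other.colors and {
            k: [write_pdb(m) for m in v] for k, v in self.states.items()
        } == {k: [write_pdb(m) for m in v] for k, v in other.states.items()}


class RecordingBackend:
    """Stores every command and the resulting session; the test/export oracle."""

    def __init__(self):
        self.session = SessionState()
        self.commands: list[RenderCommand] = []
        self.failed: list[tuple[str, str]] = []  # (model name, reason)

    # -- display contract ---------------------------------------------------

    def load_model(self, name: str, pdb_text: str, next_state: bool = False) -> int:
        """Parse and store a model; returns the 1-based state index written.

        With ``next_state`` each load appends a new state (movie frames);
        otherwise the single current state is replaced.
        """
        try:
            model = parse_pdb(pdb_text, name=name)
        except ValueError as exc:
            log.warning("unparseable PDB for %r: %s", name, exc)
            self.failed.append((name, str(exc)))
            return 0
        states = self.session.states.setdefault(name, [])
        if next_state or not states:
            states.append(model)
        else:
            states[-1] = model
        if not next_state:
            del states[:-1]
        state_index = len(states)
        self.commands.append(RenderCommand("load_model", (name, state_index, pdb_text)))
        return state_index

    def color_by_energy(self, name: str, term: str, energies: EnergyMap) -> int:
        """Color each residue of *name* by its energy; returns commands issued.

        Normalization is per message: vmin/vmax are this map's own extrema,
        so coloring always shows relative residue energies.
        """
        if name not in self.session.states:
            log.warning("energy message for unknown model %r ignored", name)
            return 0
        if not energies.values:
            return 0
        vals = energies.values.values()
        vmin, vmax = min(vals), max(vals)
        colors = self.session.colors.setdefault(name, {})
        issued = 0
        for (chain, resnum), value in energies.values.items():
            rgb = spectrum_color(value, vmin, vmax)
            colors[(chain, resnum)] = rgb
            self.commands.append(
                RenderCommand("color_residue", (name, chain, resnum, rgb))
            )
            issued += 1
        return issued

    # -- session export -----------------------------------------------------

    def export_states_pdb(self, name: str) -> str:
        """All states of one model as a multi-state PDB (MODEL/ENDMDL blocks)."""
        states = self.session.states.get(name, [])
        blocks = []
        for i, m in enumerate(states, start=1):
            body = write_pdb(m).rstrip("\n").rsplit("\n", 1)[0]  # drop END
            blocks.append(f"MODEL     {i:4d}\n{body}\nENDMDL")
        return "\n".join(blocks) + ("\nEND\n" if blocks else "")

    def export_color_table(self) -> str:
        """TSV of current colors: name, chain, resnum, r, g, b."""
        lines = ["name\tchain\tresnum\tr\tg\tb"]
        for name in sorted(self.session.colors):
            for (chain, resnum), (r, g, b) in sorted(self.session.colors[name].items()):
                lines.append(f"{name}\t{chain}\t{resnum}\t{r}\t{g}\t{b}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Viewer-script adapter (PyMOL command dialect)

_PDB_DELIM = "__END_PDB__"


def to_viewer_script(commands: list[RenderCommand]) -> str:
    """Emit a PyMOL-dialect command script, one instruction per command.

    Deterministic: the same command list always produces the same text.
    The dialect is rigid enough that :func:`parse_viewer_script` inverts it.
    """
    out = []
    for cmd in commands:
        if cmd.op == "load_model":
            name, state, pdb_text = cmd.args
            out.append(
                f'cmd.read_pdbstr("""{pdb_text}{_PDB_DELIM}""", "{name}", state={state})'
            )
        else:
            name, chain, resnum, (r, g, b) = cmd.args
            color_name = f"molsock_{chain}_{resnum}"
            out.append(
                f'cmd.set_color("{color_name}", [{r / 255:.3f}, {g / 255:.3f}, {b / 255:.3f}])'
            )
            out.append(
                f'cmd.color("{color_name}", "{name} and chain {chain} and resi {resnum}")'
            )
    return "\n".join(out) + ("\n" if out else "")


_LOAD_RE = re.compile(
    r'^cmd\.read_pdbstr\("""(?P<pdb>.*?)' + _PDB_DELIM + r'""", "(?P<name>[^"]*)", state=(?P<state>\d+)\)$',
    re.DOTALL | re.MULTILINE,
)
_SET_COLOR_RE = re.compile(
    r'^cmd\.set_color\("molsock_(?P<chain>[^_"]+)_(?P<resnum>-?\d+)", '
    r"\[(?P<r>[\d.]+), (?P<g>[\d.]+), (?P<b>[\d.]+)\]\)$"
)
_COLOR_RE = re.compile(
    r'^cmd\.color\("molsock_[^"]*", "(?P<name>.+) and chain (?P<chain>\S+) and resi (?P<resnum>-?\d+)"\)$'
)


def parse_viewer_script(text: str) -> list[RenderCommand]:
    """Invert :func:`to_viewer_script`."""
    commands: list[RenderCommand] = []
    pending_rgb: tuple[int, int, int] | None = None
    i = 0
    lines = text.split("\n")
    while i < len(lines):
        line = lines[i]
        if line.startswith("cmd.read_pdbstr("):
            block = line
            while _PDB_DELIM not in block and i + 1 < len(lines):
                i += 1
                block += "\n" + lines[i]
            m = _LOAD_RE.match(block)
            if not m:
                raise ValueError(f"unparseable load instruction near line {i + 1}")
            commands.append(
                RenderCommand(
                    "load_model", (m["name"], int(m["state"]), m["pdb"])
                )
            )
        elif line.startswith("cmd.set_color("):
            m = _SET_COLOR_RE.match(line)
            if not m:
                raise ValueError(f"unparseable set_color at line {i + 1}")
            pending_rgb = tuple(round(float(m[c]) * 255) for c in ("r", "g", "b"))
        elif line.startswith("cmd.color("):
            m = _COLOR_RE.match(line)
            if not m or pending_rgb is None:
                raise ValueError(f"unparseable color at line {i + 1}")
            commands.append(
                RenderCommand(
                    "color_residue",
                    (m["name"], m["chain"], int(m["resnum"]), pending_rgb),
                )
            )
            pending_rgb = None
        elif line.strip():
            raise ValueError(f"unknown instruction at line {i + 1}: {line!r}")
        i += 1
    return commands


def replay(commands: list[RenderCommand], backend: RecordingBackend | None = None) -> RecordingBackend:
    """Re-execute recorded commands against a (fresh) recording backend."""
    if backend is None:
        backend = RecordingBackend()
    for cmd in commands:
        if cmd.op == "load_model":
            name, state, pdb_text = cmd.args
            backend.load_model(name, pdb_text, next_state=state > 1)
        else:
            name, chain, resnum, rgb = cmd.args
            backend.session.colors.setdefault(name, {})[(chain, resnum)] = rgb
            backend.commands.append(cmd)
    return backend
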