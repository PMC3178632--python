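"""Minimal extended-XYZ trajectory I/O.

Frames carry per-atom columns ``species:S:1 pos:R:3 nucleotide:S:1
chain_id:I:1 chain_index:I:1 pol:R:3`` and a ``Time=`` comment field, so any
standard molecular viewer opens the files.  Floats are written with repr
precision and round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import state as st

__all__ = ["Frame", "write_trajectory", "read_trajectory", "frame_from_state"]

_PROPS = ("Properties=species:S:1:pos:R:3:nucleotide:S:1:chain_id:I:1:"
          "chain_index:I:1:pol:R:3")


@dataclass
class Frame:
    time: float
    species: list          # names
    pos: np.ndarray        # (N, 3)
    nucleotide: list       # names
    chain_id: np.ndarray
    chain_index: np.ndarray
    pol: np.ndarray


def frame_from_state(state: st.SystemState, time: float) -> Frame:
    return Frame(
        time=time,
        species=[st.SPECIES_NAMES[int(s)] for s in state.species],
        pos=state.pos.copy(),
        nucleotide=[st.NUC_NAMES[int(x)] for x in state.nucleotide],
        chain_id=state.chain_id.copy(),
        chain_index=state.chain_index.copy(),
        pol=state.pol.copy(),
    )


def write_trajectory(path, frames) -> None:
    with open(path, "w") as fh:
        for fr in frames:
            n = len(fr.pos)
            fh.write(f"{n}\n")
            fh.write(f"{_PROPS} Time={float(fr.time)!r}\n")
            for i in range(n):
                x, y, z = (float(v) for v in fr.pos[i])
                px, py, pz = (float(v) for v in fr.pol[i])
                fh.write(f"{fr.species[i]} {x!r} {y!r} {z!r} "
                         f"{fr.nucleotide[i]} {int(fr.chain_id[i])} "
                         f"{int(fr.chain_index[i])} {px!r} {py!r} {pz!r}\n")


def read_trajectory(path, stride: int = 1):
    """Read frames back; ``stride`` keeps every stride-th frame."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    idx = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k])
        except ValueError as exc:
            raise ValueError(f"malformed frame header at line {k + 1}") from exc
        comment = lines[k + 1]
        time = None
        for tok in comment.split():
            if tok.startswith("Time="):
                time = float(tok[5:])
        if time is None or _PROPS.split()[0] not in comment:
            raise ValueError(f"malformed comment line in frame {idx}")
        body = lines[k + 2: k + 2 + n]
        if len(body) != n:
            raise ValueError(f"truncated frame {idx}")
        if idx % stride == 0:
            species, nuc = [], []
            pos = np.empty((n, 3))
            pol = np.empty((n, 3))
            cid = np.empty(n, np.int32)
            cix = np.empty(n, np.int32)
            for i, line in enumerate(body):
                parts = line.split()
                if len(parts) != 10:
                    raise ValueError(f"malformed atom line in frame {idx}, atom {i}")
                species.append(parts[0])
                pos[i] = [float(p) for p in parts[1:4]]
                nuc.append(parts[4])
                cid[i] = int(parts[5])
                cix[i] = int(parts[6])
                pol[i] = [float(p) for p in parts[7:10]]
            frames.append(Frame(time, species, pos, nuc, cid, cix, pol))
        k += 2 + n
        idx += 1
    return frames
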