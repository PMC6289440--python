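"""Reference metadata for the 32-channel adipose-tissue fatty-acid panel.

Each channel is a fatty acid quantified by gas chromatography as a percentage
of total fatty acids. The default means/SDs and the seven-block pattern
memberships describe a middle-aged Danish cohort; they drive the synthetic
generator and the table renderers.

Trans isomers whose printed chain notation collides with the cis form carry a
``t`` suffix in the machine identifier (e.g. ``18:1n-9t`` is elaidic acid,
``18:1n-9`` oleic acid).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Channel:
    """One fatty-acid channel: identifier, common name, marginal moments, block."""

    id: str
    common_name: str
    mean: float        # % of total fatty acids
    sd: float          # % of total fatty acids
    block: str | None  # pattern membership; None = in no pattern


# SDs printed as "<0.1" are encoded as 0.05.
CHANNELS: tuple[Channel, ...] = (
    Channel("12:0", "Lauric acid", 0.4, 0.1, "TT1"),
    Channel("14:0", "Myristic acid", 2.7, 0.5, "TT1"),
    Channel("14:1n-5", "Myristoleic acid", 0.4, 0.1, "TT6"),
    Channel("15:0", "Pentadecanoic acid", 0.3, 0.1, "TT1"),
    Channel("16:0", "Palmitic acid", 20.2, 2.0, "TT1"),
    Channel("16:1n-7", "Palmitoleic acid", 6.6, 1.6, "TT6"),
    Channel("17:0", "Heptadecanoic acid", 0.2, 0.05, "TT1"),
    Channel("18:0", "Stearic acid", 3.5, 1.0, "TT1"),
    Channel("18:1n-6+8t", "trans-octadecenoic acid (d12t+d10t)", 0.3, 0.1, "TT2"),
    Channel("18:1n-9t", "Elaidic acid", 0.6, 0.2, "TT2"),
    Channel("18:1n-8t", "trans-octadecenoic acid (d10t)", 0.3, 0.1, "TT2"),
    Channel("18:1n-7t", "Vaccenic acid", 0.3, 0.1, "TT1"),
    Channel("18:1n-10+12t", "trans-octadecenoic acid (d8t+d6t)", 1.5, 0.4, "TT2"),
    Channel("18:1n-9", "Oleic acid", 44.0, 2.0, None),
    Channel("18:1n-7", "Asclepic acid", 2.0, 0.4, "TT4"),
    Channel("18:2n-7t", "Rumenic acid", 0.4, 0.1, "TT6"),
    Channel("18:2n-6", "Linoleic acid", 10.7, 1.9, "TT7"),
    Channel("18:3n-3", "alpha-linolenic acid", 0.8, 0.2, "TT7"),
    Channel("18:3n-6", "gamma-linolenic acid", 0.1, 0.05, None),
    Channel("19:0", "Nonadecanoic acid", 0.1, 0.05, "TT1"),
    Channel("20:0", "Arachidic acid", 0.2, 0.1, "TT5"),
    Channel("20:1n-9", "n-9 eicosenoic acid", 0.8, 0.2, "TT5"),
    Channel("20:1n-11", "n-11 eicosenoic acid", 0.2, 0.1, "TT5"),
    Channel("20:2n-6", "Eicosadienoic acid", 0.2, 0.05, "TT4"),
    Channel("20:3n-6", "Dihomo-gamma-linolenic acid", 0.2, 0.1, "TT4"),
    Channel("20:4n-3", "Eicosatetraenoic acid", 0.1, 0.05, "TT3"),
    Channel("20:4n-6", "Arachidonic acid", 0.4, 0.1, "TT4"),
    Channel("20:5n-3", "Eicosapentaenoic acid", 0.1, 0.05, "TT3"),
    Channel("22:1n-9", "Erucic acid", 0.1, 0.05, "TT5"),
    Channel("22:4n-6", "Docosatetraenoic acid", 0.1, 0.05, "TT4"),
    Channel("22:5n-3", "Docosapentaenoic acid", 0.3, 0.1, "TT3"),
    Channel("22:6n-3", "Docosahexaenoic acid", 0.3, 0.1, "TT3"),
)

CHANNEL_IDS: tuple[str, ...] = tuple(c.id for c in CHANNELS)
COMMON_NAMES: dict[str, str] = {c.id: c.common_name for c in CHANNELS}

#: Pattern label -> member channel ids, in panel order.
BLOCKS: dict[str, tuple[str, ...]] = {}
for _c in CHANNELS:
    if _c.block is not None:
        BLOCKS.setdefault(_c.block, ())
        BLOCKS[_c.block] += (_c.id,)

#: Channels belonging to no pattern (oleic and gamma-linolenic acid).
UNASSIGNED: tuple[str, ...] = tuple(c.id for c in CHANNELS if c.block is None)
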