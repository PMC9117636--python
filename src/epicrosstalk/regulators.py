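"""The packaged catalog of 43 epigenetic regulators and their roles.

Covers the writers/erasers of H3K4 methylation, the acetylases/deacetylases
of H3K27ac, and the writers/readers/erasers of m6A.  The 22 m6A regulators
(10 writers + 10 readers + 2 erasers) are the family used for CEG screening.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RegulatorSet", "default_regulators", "ROLES"]

ROLES = (
    "histone_writer",
    "histone_eraser",
    "histone_acetylase",
    "histone_deacetylase",
    "m6a_writer",
    "m6a_reader",
    "m6a_eraser",
)

_DEFAULT: dict[str, str] = {
    # H3K4 methyltransferases
    "SETD1A": "histone_writer",
    "SETD1B": "histone_writer",
    "KMT2A": "histone_writer",
    "KMT2B": "histone_writer",
    "KMT2C": "histone_writer",
    "KMT2D": "histone_writer",
    # histone demethylases
    "KDM1A": "histone_eraser",
    "KDM1B": "histone_eraser",
    "KDM2A": "histone_eraser",
    "KDM2B": "histone_eraser",
    "KDM5A": "histone_eraser",
    "KDM5B": "histone_eraser",
    "KDM5C": "histone_eraser",
    "KDM5D": "histone_eraser",
    # histone acetylases
    "CREBBP": "histone_acetylase",
    "EP300": "histone_acetylase",
    # histone deacetylases
    "HDAC1": "histone_deacetylase",
    "HDAC2": "histone_deacetylase",
    "HDAC3": "histone_deacetylase",
    "HDAC8": "histone_deacetylase",
    "HDAC11": "histone_deacetylase",
    # m6A writers
    "METTL14": "m6a_writer",
    "METTL3": "m6a_writer",
    "METTL16": "m6a_writer",
    "RBM15": "m6a_writer",
    "RBM15B": "m6a_writer",
    "ZC3H13": "m6a_writer",
    "ZCCHC4": "m6a_writer",
    "WTAP": "m6a_writer",
    "CBLL1": "m6a_writer",
    "VIRMA": "m6a_writer",
    # m6A readers
    "YTHDC1": "m6a_reader",
    "YTHDC2": "m6a_reader",
    "YTHDF1": "m6a_reader",
    "YTHDF2": "m6a_reader",
    "YTHDF3": "m6a_reader",
    "IGF2BP1": "m6a_reader",
    "IGF2BP2": "m6a_reader",
    "IGF2BP3": "m6a_reader",
    "HNRNPA2B1": "m6a_reader",
    "HNRNPC": "m6a_reader",
    # m6A erasers
    "ALKBH5": "m6a_eraser",
    "FTO": "m6a_eraser",
}


@dataclass(frozen=True)
class RegulatorSet:
    """Map of regulator gene symbol -> role."""

    regulators: dict[str, str]

    def __post_init__(self) -> None:
        bad = {r for r in self.regulators.values() if r not in ROLES}
        if bad:
            raise ValueError(f"unknown regulator roles: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.regulators)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.regulators

    def with_role(self, *roles: str) -> list[str]:
        for role in roles:
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r}")
        return sorted(g for g, r in self.regulators.items() if r in roles)

    @property
    def all(self) -> list[str]:
        return sorted(self.regulators)

    @property
    def m6a(self) -> list[str]:
        """The m6A writer/reader/eraser family (22 by default)."""
        return self.with_role("m6a_writer", "m6a_reader", "m6a_eraser")

    @property
    def m6a_writers_readers(self) -> list[str]:
        return self.with_role("m6a_writer", "m6a_reader")

    @property
    def m6a_erasers(self) -> list[str]:
        return self.with_role("m6a_eraser")


def default_regulators() -> RegulatorSet:
    """The packaged 43-regulator catalog."""
    return RegulatorSet(dict(_DEFAULT))
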