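"""Binding-site confidence aggregation from per-residue pLDDT.

Structure-prediction networks deposit their local confidence estimate
(pLDDT, 0-100) in the B-factor channel. AlphaFold 2 writes one value per
residue (every atom of the residue carries it); AlphaFold 3 writes one
value per atom. Both conventions are unified by averaging the atomic
values per residue, which is exact for the residue-level convention.

A binding site is a named list of key residues (author numbering plus the
expected one-letter code, which guards against numbering drift). For each
key residue the confidence is averaged over a window of sequence
neighbors, then across the chains of the homomeric assembly; the site's
global average is the mean of the key residues' windowed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import StructureModel

#: the five nearest sequence neighbors, tie toward the N-terminus
DEFAULT_NEIGHBOR_OFFSETS: tuple[int, ...] = (-3, -2, -1, 1, 2)

# Key residues of the human P2X7 receptor binding pockets (UniProt Q99572
# author numbering). The agonist (ATP) pocket and the adjacent antagonist
# pocket; position 312 is valine in the canonical sequence.
ORTHOSTERIC_KEY_RESIDUES: tuple[tuple[int, str], ...] = (
    (64, "K"), (66, "K"), (189, "T"), (292, "N"), (294, "R"), (311, "K"),
)
ALLOSTERIC_KEY_RESIDUES: tuple[tuple[int, str], ...] = (
    (88, "F"), (95, "F"), (103, "F"), (105, "M"), (293, "F"), (312, "V"),
)


@dataclass
class ConfidenceMap:
    """Per-residue mean confidence: (chain id, residue number) -> pLDDT."""

    entries: dict[tuple[str, int], float]

    def __getitem__(self, key: tuple[str, int]) -> float:
        return self.entries[key]

    def get(self, key: tuple[str, int]) -> float | None:
        return self.entries.get(key)


@dataclass
class SiteDefinition:
    """A named binding site: key residues with expected identity and the
    neighbor window used for per-residue confidence."""

    name: str
    key_residues: list[tuple[int, str]]
    neighbor_offsets: tuple[int, ...] = DEFAULT_NEIGHBOR_OFFSETS

    def __post_init__(self) -> None:
        self.key_residues = [(int(n), c) for n, c in self.key_residues]
        self.neighbor_offsets = tuple(int(o) for o in self.neighbor_offsets)
        if any(n <= 0 for n, _ in self.key_residues):
            raise ValueError(f"site {self.name}: residue numbers must be positive")
        if 0 in self.neighbor_offsets:
            raise ValueError(f"site {self.name}: neighbor offsets must exclude 0")


def orthosteric_site(neighbor_offsets: tuple[int, ...] = DEFAULT_NEIGHBOR_OFFSETS) -> SiteDefinition:
    return SiteDefinition("orthosteric", list(ORTHOSTERIC_KEY_RESIDUES), neighbor_offsets)


def allosteric_site(neighbor_offsets: tuple[int, ...] = DEFAULT_NEIGHBOR_OFFSETS) -> SiteDefinition:
    return SiteDefinition("allosteric", list(ALLOSTERIC_KEY_RESIDUES), neighbor_offsets)


@dataclass
class SiteConfidenceReport:
    """Per-key-residue windowed mean confidences and their global average."""

    site_name: str
    per_residue: list[tuple[str, float]]
    global_average: float
    n_chains_used: int
    missing: list[str] = field(default_factory=list)
    window_sizes: dict[str, int] = field(default_factory=dict)

    def rounded(self, ndigits: int = 2) -> "SiteConfidenceReport":
        """Reporting copy at table precision (2 decimals by default)."""
        return SiteConfidenceReport(
            site_name=self.site_name,
            per_residue=[(lab, round(v, ndigits)) for lab, v in self.per_residue],
            global_average=round(self.global_average, ndigits),
            n_chains_used=self.n_chains_used,
            missing=list(self.missing),
            window_sizes=dict(self.window_sizes),
        )


def residue_confidence(model: StructureModel, mode: str = "atom_mean") -> ConfidenceMap:
    """Extract per-residue confidence from the B-factor channel.

    ``atom_mean`` averages over all atoms of the residue (exact for
    residue-level files where all atoms share one value); ``ca_only``
    takes the Cα value.
    """
    if model.is_experimental:
        raise ValueError(
            f"model {model.id} is flagged experimental: its B-factors are not pLDDT"
        )
    if mode not in ("atom_mean", "ca_only"):
        raise ValueError(f"unknown mode {mode!r}")
    entries: dict[tuple[str, int], float] = {}
    skipped: list[str] = []
    for chain in model.chains:
        for res in chain.residues:
            if mode == "atom_mean":
                values = [a.bvalue for a in res.atoms]
            else:
                values = [a.bvalue for a in res.atoms if a.name == "CA"]
            if not values:
                skipped.append(f"{chain.id}/{res.label}")
                continue
            entries[(chain.id, res.number)] = float(np.mean(values))
    if skipped:
        warnings.warn(f"residues without usable atoms excluded: {skipped}", stacklevel=2)
    return ConfidenceMap(entries=entries)


def site_confidence(
    conf: ConfidenceMap,
    model: StructureModel,
    site: SiteDefinition,
    chain_policy: str = "average_all",
) -> SiteConfidenceReport:
    """Aggregate confidence over a site's key residues.

    For each key residue the window is the residue plus its configured
    sequence neighbors, clipped to residues present in the chain; the
    windowed mean is averaged over chains (``average_all``) or taken from
    one chain (``single:<id>``). The global average is the arithmetic
    mean of the key residues' values.
    """
    if chain_policy == "average_all":
        chains = model.chains
    elif chain_policy.startswith("single:"):
        chains = [model.chain(chain_policy.split(":", 1)[1])]
    else:
        raise ValueError(f"unknown chain policy {chain_policy!r}")

    per_residue: list[tuple[str, float]] = []
    missing: list[str] = []
    window_sizes: dict[str, int] = {}
    chains_used: set[str] = set()
    for number, expected in site.key_residues:
        label = f"{expected}{number}"
        chain_values: list[float] = []
        eff_window = 0
        for chain in chains:
            if not chain.has_residue(number):
                continue
            found = chain.residue(number).aa_code
            if found != expected:
                raise ValueError(
                    f"site {site.name}: residue {number} in chain {chain.id} is "
                    f"{found!r}, expected {expected!r} — check model numbering"
                )
            window_numbers = [number] + [number + o for o in site.neighbor_offsets]
            values = [
                conf.get((chain.id, n))
                for n in window_numbers
                if conf.get((chain.id, n)) is not None
            ]
            if not values:
                continue
            chain_values.append(float(np.mean(values)))
            eff_window = max(eff_window, len(values))
            chains_used.add(chain.id)
        if not chain_values:
            missing.append(label)
            continue
        per_residue.append((label, float(np.mean(chain_values))))
        window_sizes[label] = eff_window
    if not per_residue:
        raise ValueError(f"site {site.name}: no key residue found in model {model.id}")
    return SiteConfidenceReport(
        site_name=site.name,
        per_residue=per_residue,
        global_average=aggregate_global_mean([v for _, v in per_residue]),
        n_chains_used=len(chains_used),
        missing=missing,
        window_sizes=window_sizes,
    )


def aggregate_global_mean(per_residue_means: list[float]) -> float:
    """Arithmetic mean of per-residue values — the site's global average."""
    if len(per_residue_means) == 0:
        raise ValueError("cannot average an empty list of per-residue means")
    return float(np.mean(per_residue_means))


def rank_site_residues(report: SiteConfidenceReport) -> list[tuple[str, float]]:
    """Key residues ordered by descending confidence; ties by residue number."""
    if not report.per_residue:
        raise ValueError("empty report")

    def resnum(label: str) -> int:
        return int("".join(ch for ch in label if ch.isdigit()))

    return sorted(report.per_residue, key=lambda item: (-item[1], resnum(item[0])))


def report_to_rows(report: SiteConfidenceReport, ndigits: int = 2) -> list[tuple[str, str]]:
    """Table rows (Residue, pLDDT mean) plus the global-average footer."""
    rounded = report.rounded(ndigits)
    rows = [(lab, f"{v:.{ndigits}f}") for lab, v in rounded.per_residue]
    rows.append(("Global average", f"{rounded.global_average:.{ndigits}f}"))
    return rows
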