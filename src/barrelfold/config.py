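"""Run configuration: geometry, filter and energy parameters with defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline.

    Geometry
    --------
    h : rise per residue along a strand (Å).
    d : distance between adjacent strands (Å).
    membrane_thickness : bilayer thickness (Å); 30 Å corresponds to a
        membrane about 8 residues thick for typical strand tilts.
    min_span_residues : nominal residue count needed to cross the membrane.

    Enumeration
    -----------
    n_min, n_max : even strand counts scanned for a barrel (8..22).
    Shear numbers S are scanned over the even values in [n, 2n].
    shear_min, shear_max : grid of per-pair relative shears; known barrels
        are right-slanted, hence a non-negative default grid.

    Filter
    ------
    rho : block-filter threshold ρ; each scored block pays -log ρ, so
        ρ < 1 is a per-block bonus (a permissive filter).
    zeta_minus, zeta_plus : hydrophobic-side lower / hydrophilic-side upper
        bounds on the two side-average hydropathies (Kyte-Doolittle units).
    block_len : l, the block length of the information filter.
    pseudocount : Laplace-style smoothing constant for block frequencies;
        kept well below 1 because the 20^l block space dwarfs any realistic
        training mass and add-one smoothing would drown the signal.
    prune_overlap_fraction, max_overlapping_candidates : non-maximum
        suppression of near-duplicate strand candidates during graph
        construction (overlap fraction of the shorter segment; variants
        kept per region).

    Lengths
    -------
    strand_len_bounds, loop_len_bounds : admissible residue counts;
    max_leader, max_trailer : bound on the free N-/C-terminal fragments.

    Energy
    ------
    hb_reward : pseudo-energy gained per aligned residue pair (H-bond term).
    pair_scale : scale of the side-chain pair term -scale*H(a)*H(b) applied
        to aligned pairs facing the same environment.
    w_propensity : weight of the strand-propensity term inside E_intr.
    loop_penalty : pseudo-energy of an infeasible turn/loop.
    loop_span_factor : a loop crossing t barrel positions must be at least
        loop_span_factor*t residues long.

    Classification
    --------------
    classify_threshold : minimum per-strand criterion C/n for a TMB call.
    energy_window : relative window above the minimum energy used when
        reporting low-energy permutations in a landscape scan.
    """

    # geometry
    h: float = 3.3
    d: float = 4.4
    membrane_thickness: float = 30.0
    min_span_residues: int = 8
    # enumeration
    n_min: int = 8
    n_max: int = 22
    shear_min: int = 0
    shear_max: int = 4
    # filter
    rho: float = 2.0 / 3.0
    zeta_minus: float = -1.0
    zeta_plus: float = 1.0
    block_len: int = 3
    pseudocount: float = 0.1
    prune_overlap_fraction: float = 0.5
    max_overlapping_candidates: int = 2
    # lengths
    strand_len_bounds: tuple[int, int] = (6, 22)
    loop_len_bounds: tuple[int, int] = (2, 18)
    max_leader: int = 50
    max_trailer: int = 50
    # energy
    hb_reward: float = 0.5
    pair_scale: float = 0.2
    w_propensity: float = 2.0
    loop_penalty: float = 1000.0
    loop_span_factor: int = 2
    # classification
    classify_threshold: float = 0.85
    energy_window: float = 0.02

    def __post_init__(self) -> None:
        if self.h <= 0 or self.d <= 0 or self.membrane_thickness <= 0:
            raise ValueError("h, d and membrane_thickness must be positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if not (8 <= self.n_min <= self.n_max <= 22):
            raise ValueError("n range must lie within [8, 22]")
        if self.n_min % 2 or self.n_max % 2:
            raise ValueError("n_min and n_max must be even")
        if self.block_len < 1:
            raise ValueError("block_len must be >= 1")
        lo, hi = self.strand_len_bounds
        if not 2 <= lo <= hi:
            raise ValueError("bad strand_len_bounds")
        lo, hi = self.loop_len_bounds
        if not 2 <= lo <= hi:
            raise ValueError("bad loop_len_bounds (minimum gap is 2)")

    def n_values(self) -> list[int]:
        return list(range(self.n_min, self.n_max + 1, 2))

    def s_values(self, n: int) -> list[int]:
        """Even shear numbers admitted for an n-strand barrel: S in [n, 2n]."""
        return list(range(n if n % 2 == 0 else n + 1, 2 * n + 1, 2))

    def shear_grid(self) -> range:
        return range(self.shear_min, self.shear_max + 1)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML file mirroring the RunConfig fields (subset allowed)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config YAML must be a mapping")
    for key in ("strand_len_bounds", "loop_len_bounds"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    data = asdict(config)
    data["strand_len_bounds"] = list(config.strand_len_bounds)
    data["loop_len_bounds"] = list(config.loop_len_bounds)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
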