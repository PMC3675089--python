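"""Territory geometry and acquisition on the landscape grid.

Territories are fixed-area square blocks placed on a coarse candidate
lattice (stride of half a block side), clipped to the grid.  A block's
score is the sum of per-cell habitat scores times cell area; because
scores are uniform within polygons, each candidate reduces to a static
vector of per-polygon cell counts dotted with the day's per-polygon
score.  An occupied territory whose score reaches the split threshold
may be divided along its longer axis when both halves stay acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import FIELD_LIKE_ELEMENTS, LandscapeGrid
from .params import SkylarkParams


@dataclass
class Rect:
    r0: int
    c0: int
    nr: int
    nc: int

    @property
    def centre(self) -> tuple[int, int]:
        return self.r0 + (self.nr - 1) // 2, self.c0 + (self.nc - 1) // 2

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.r0 + self.nr <= other.r0
            or other.r0 + other.nr <= self.r0
            or self.c0 + self.nc <= other.c0
            or other.c0 + other.nc <= self.c0
        )

    def halves(self) -> tuple["Rect", "Rect"]:
        """Split along the longer axis into two equal-as-possible halves."""
        if self.nr >= self.nc:
            top = self.nr // 2
            return (
                Rect(self.r0, self.c0, top, self.nc),
                Rect(self.r0 + top, self.c0, self.nr - top, self.nc),
            )
        left = self.nc // 2
        return (
            Rect(self.r0, self.c0, self.nr, left),
            Rect(self.r0, self.c0 + left, self.nr, self.nc - left),
        )


@dataclass
class Territory:
    territory_id: int
    owner_id: int
    rect: Rect
    poly_counts: np.ndarray      # cells per polygon index within the block
    centre: tuple[int, int]
    centre_poly: int             # polygon id at the centre cell

    def score(self, score_per_m2: np.ndarray, cell_area: float) -> float:
        return float(self.poly_counts @ score_per_m2) * cell_area


def block_rect(centre: tuple[int, int], block_cells: int, shape: tuple[int, int]) -> Rect:
    """The square block of side ``block_cells`` centred on a cell, clipped."""
    r0 = max(0, centre[0] - block_cells // 2)
    c0 = max(0, centre[1] - block_cells // 2)
    r1 = min(shape[0], centre[0] - block_cells // 2 + block_cells)
    c1 = min(shape[1], centre[1] - block_cells // 2 + block_cells)
    return Rect(r0, c0, r1 - r0, c1 - c0)


def rect_poly_counts(grid: LandscapeGrid, rect: Rect) -> np.ndarray:
    sub = grid.index_raster[rect.r0 : rect.r0 + rect.nr, rect.c0 : rect.c0 + rect.nc]
    return np.bincount(sub.ravel(), minlength=len(grid.polygons)).astype(np.float64)


def evaluate_territory(
    grid: LandscapeGrid,
    centre: tuple[int, int],
    score_per_m2: np.ndarray,
    params: SkylarkParams,
) -> tuple[Rect, float, bool]:
    """Candidate territory at ``centre``: (block rect, total score, acceptable).

    The block has the configured territory area (clipped to the grid);
    acceptability requires the total score to reach MINFEMACCEPTSCORE.
    """
    block_cells = max(1, int(round(np.sqrt(params.territory_area_m2) / grid.cell_size)))
    rect = block_rect(centre, block_cells, grid.shape)
    counts = rect_poly_counts(grid, rect)
    total = float(counts @ score_per_m2) * grid.cell_size**2
    return rect, total, total >= params.MINFEMACCEPTSCORE


class TerritoryManager:
    """Candidate lattice, occupancy tracking and acquisition/splitting."""

    def __init__(self, grid: LandscapeGrid, params: SkylarkParams):
        self.grid = grid
        self.params = params
        self.cell_area = grid.cell_size**2
        self.block_cells = max(
            1, int(round(np.sqrt(params.territory_area_m2) / grid.cell_size))
        )
        stride = max(1, self.block_cells // 2)
        h, w = grid.shape
        field_like_poly = np.array(
            [p.element_type in FIELD_LIKE_ELEMENTS for p in grid.polygons]
        )
        centres, rects, counts = [], [], []
        for r in range(stride // 2, h, stride):
            for c in range(stride // 2, w, stride):
                if not field_like_poly[grid.index_raster[r, c]]:
                    continue
                rect = block_rect((r, c), self.block_cells, grid.shape)
                centres.append((r, c))
                rects.append(rect)
                counts.append(rect_poly_counts(grid, rect))
        self.centres = centres
        self.rects = rects
        self.counts = (
            np.vstack(counts) if counts else np.zeros((0, len(grid.polygons)))
        )
        n = len(centres)
        self._r0 = np.array([rc.r0 for rc in rects], dtype=np.int32)
        self._r1 = np.array([rc.r0 + rc.nr for rc in rects], dtype=np.int32)
        self._c0 = np.array([rc.c0 for rc in rects], dtype=np.int32)
        self._c1 = np.array([rc.c0 + rc.nc for rc in rects], dtype=np.int32)
        self.blocked = np.zeros(n, dtype=np.int32)
        self.territories: dict[int, Territory] = {}
        self._next_id = 1

    # -- occupancy bookkeeping --

    def _overlap_mask(self, rect: Rect) -> np.ndarray:
        return (
            (self._r0 < rect.r0 + rect.nr)
            & (self._r1 > rect.r0)
            & (self._c0 < rect.c0 + rect.nc)
            & (self._c1 > rect.c0)
        )

    def _claim_rect(self, rect: Rect) -> None:
        self.blocked += self._overlap_mask(rect)

    def _release_rect(self, rect: Rect) -> None:
        self.blocked -= self._overlap_mask(rect)

    def candidate_scores(self, score_per_m2: np.ndarray) -> np.ndarray:
        return (self.counts @ score_per_m2) * self.cell_area

    def _make_territory(self, owner_id: int, rect: Rect) -> Territory:
        counts = rect_poly_counts(self.grid, rect)
        centre = rect.centre
        t = Territory(
            territory_id=self._next_id,
            owner_id=owner_id,
            rect=rect,
            poly_counts=counts,
            centre=centre,
            centre_poly=self.grid.polygon_at(*centre).poly_id,
        )
        self._next_id += 1
        self.territories[t.territory_id] = t
        self._claim_rect(rect)
        return t

    def release(self, territory: Territory) -> None:
        self._release_rect(territory.rect)
        del self.territories[territory.territory_id]

    # -- acquisition --

    def try_acquire(
        self, owner_id: int, score_per_m2: np.ndarray, allow_split: bool = True
    ) -> tuple[Territory | None, tuple | None]:
        """Claim the best acceptable free candidate, else try a split.

        Returns (territory or None, split_info).  When a split happened,
        split_info is (previous owner id, that owner's shrunk territory)
        so the caller can update the owner's reference.
        """
        params = self.params
        if len(self.centres):
            scores = self.candidate_scores(score_per_m2)
            scores[self.blocked > 0] = -np.inf
            best = int(np.argmax(scores))
            if scores[best] >= params.MINFEMACCEPTSCORE:
                return self._make_territory(owner_id, self.rects[best]), None
        if allow_split:
            return self._try_split(owner_id, score_per_m2)
        return None, None

    def _try_split(
        self, owner_id: int, score_per_m2: np.ndarray
    ) -> tuple[Territory | None, tuple | None]:
        params = self.params
        threshold = params.split_threshold_multiplier * params.MINFEMACCEPTSCORE
        for t in list(self.territories.values()):
            if t.score(score_per_m2, self.cell_area) < threshold:
                continue
            a, b = t.rect.halves()
            if min(a.nr, a.nc, b.nr, b.nc) < 1:
                continue
            sa = float(rect_poly_counts(self.grid, a) @ score_per_m2) * self.cell_area
            sb = float(rect_poly_counts(self.grid, b) @ score_per_m2) * self.cell_area
            if sa < params.MINFEMACCEPTSCORE or sb < params.MINFEMACCEPTSCORE:
                continue
            keep, give = (a, b) if sa >= sb else (b, a)
            old_owner = t.owner_id
            self.release(t)
            kept = self._make_territory(old_owner, keep)
            new = self._make_territory(owner_id, give)
            return new, (old_owner, kept)
        return None, None


def acquire_territories(
    grid: LandscapeGrid,
    male_ids: list[int],
    score_per_m2: np.ndarray,
    params: SkylarkParams,
    rng: np.random.Generator,
    manager: TerritoryManager | None = None,
) -> tuple[dict[int, Territory], list[int]]:
    """One day of territory acquisition for a set of searching males.

    Males are processed in rng-shuffled order; each claims the best
    acceptable non-overlapping candidate (or a split of a rich occupied
    territory).  Returns (assignments, remaining floaters).
    """
    manager = manager or TerritoryManager(grid, params)
    order = rng.permutation(len(male_ids))
    assigned: dict[int, Territory] = {}
    floaters: list[int] = []
    for i in order:
        mid = male_ids[int(i)]
        territory, _ = manager.try_acquire(mid, score_per_m2)
        if territory is None:
            floaters.append(mid)
        else:
            assigned[mid] = territory
    return assigned, floaters
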