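"""Residue-residue contact maps, interface composition, helix-pairing
orientation, interface periodicity and the bundle-domain exclusion screen."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

DEFAULT_CONTACT_CUTOFF = 0.5  # nm
DEFAULT_MIN_COUNT = 5         # strict ">" filter
DEFAULT_WINDOW_US = 0.1       # last 100 ns-equivalent
DEFAULT_N_FRAMES = 5


class ContactError(ValueError):
    pass


def min_distance_series(ensemble, replicate: int) -> pd.DataFrame:
    """(time, min inter-protomer bead distance) for one replicate.

    Uses a KD-tree on the larger protomer; see tests for the brute-force
    oracle equivalence.
    """
    rows = []
    for fi in range(ensemble.n_frames):
        a, b = ensemble.bead_coords(replicate, fi)
        tree = cKDTree(a)
        d, _ = tree.query(b, k=1)
        rows.append((ensemble.times[fi], float(d.min())))
    return pd.DataFrame(rows, columns=["time_us", "min_distance_nm"])


def min_distance_brute(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """O(N^2) reference for the minimum inter-protomer bead distance."""
    return float(cdist(coords_a, coords_b).min())


@dataclass
class ContactMap:
    counts: np.ndarray            # (n_res, n_res)
    residues: np.ndarray          # residue numbers indexing rows/columns
    n_frames_per_replicate: int
    window_us: tuple[float, float]
    res_to_idx: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.res_to_idx = {int(r): i for i, r in enumerate(self.residues)}

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def helix_block(self, template, helix_a: str, helix_b: str) -> np.ndarray:
        ia = [self.res_to_idx[r] for r in template.residues_of_helix(helix_a)]
        ib = [self.res_to_idx[r] for r in template.residues_of_helix(helix_b)]
        return self.counts[np.ix_(ia, ib)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.residues, columns=self.residues)


def _window_frame_indices(ensemble, window_us: float, n_frames: int) -> np.ndarray:
    """Equally spaced stored-frame indices spanning the trailing window."""
    t_end = ensemble.times[-1]
    t_start = t_end - window_us
    if t_start < ensemble.times[0] - 1e-9:
        raise ContactError(
            f"window of {window_us} us extends before the first stored frame"
        )
    targets = np.linspace(t_start, t_end, n_frames)
    idx = np.unique([int(np.argmin(np.abs(ensemble.times - t))) for t in targets])
    if len(idx) < n_frames:
        raise ContactError(
            f"only {len(idx)} distinct stored frames available in the last "
            f"{window_us} us; need {n_frames}"
        )
    return idx


def contact_pairs_frame(coords_a, coords_b, residues_a, residues_b,
                        cutoff: float = DEFAULT_CONTACT_CUTOFF):
    """Unique residue pairs (i on A, j on B) with any bead pair within cutoff."""
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    pairs = tree_a.query_ball_tree(tree_b, cutoff)
    out = set()
    for ia, hits in enumerate(pairs):
        for ib in hits:
            out.add((int(residues_a[ia]), int(residues_b[ib])))
    return out


def residue_contact_map(
    ensemble,
    template,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    n_frames: int = DEFAULT_N_FRAMES,
    window_us: float = DEFAULT_WINDOW_US,
    replicates=None,
) -> ContactMap:
    """Ensemble-summed residue contact map.

    A residue pair (i on A, j on B) counts once per frame if any bead of i is
    within ``cutoff`` of any bead of j; both labelings (i, j) and (j, i) are
    accumulated, so the homodimer ensemble map is symmetric by construction.
    """
    residues = template.residues
    n = len(residues)
    res_idx = {int(r): i for i, r in enumerate(residues)}
    counts = np.zeros((n, n))
    frame_ids = _window_frame_indices(ensemble, window_us, n_frames)
    reps = range(ensemble.n_replicates) if replicates is None else replicates
    res_of_bead = ensemble.template.residue_index
    for r in reps:
        for fi in frame_ids:
            a, b = ensemble.bead_coords(r, fi)
            for i, j in contact_pairs_frame(a, b, res_of_bead, res_of_bead, cutoff):
                counts[res_idx[i], res_idx[j]] += 1
                counts[res_idx[j], res_idx[i]] += 1
    return ContactMap(
        counts=counts, residues=residues,
        n_frames_per_replicate=len(frame_ids),
        window_us=(float(ensemble.times[-1] - window_us), float(ensemble.times[-1])),
    )


def filter_contacts(cmap: ContactMap, min_count: int = DEFAULT_MIN_COUNT) -> pd.DataFrame:
    """Sparse contact list keeping pairs occurring strictly more than
    ``min_count`` times, sorted by count descending."""
    ii, jj = np.nonzero(cmap.counts > min_count)
    rows = [(int(cmap.residues[i]), int(cmap.residues[j]),
             float(cmap.counts[i, j])) for i, j in zip(ii, jj)]
    df = pd.DataFrame(rows, columns=["res_i", "res_j", "count"])
    return df.sort_values(["count", "res_i", "res_j"],
                          ascending=[False, True, True]).reset_index(drop=True)


@dataclass
class InterfaceSummary:
    per_helix: pd.DataFrame       # helix, domain, contact total
    bundle_fraction: float
    interface_helices: list[str]


def interface_summary(cmap: ContactMap, template,
                      min_helix_total: float = 0.0) -> InterfaceSummary:
    """Per-helix contact totals and the bundle-domain share of the interface."""
    helix_of_res = {r: template.helix_of_residue[r] for r in cmap.residues}
    row_tot = cmap.counts.sum(axis=1)
    helices = sorted(set(helix_of_res.values()))
    totals = {h: 0.0 for h in helices}
    for k, r in enumerate(cmap.residues):
        totals[helix_of_res[int(r)]] += row_tot[k]
    per_helix = pd.DataFrame(
        [(h, template.domain_of_helix.get(h, "other"), totals[h])
         for h in helices],
        columns=["helix", "domain", "contact_total"],
    )
    total = per_helix["contact_total"].sum()
    bundle = per_helix.loc[per_helix["domain"] == "bundle", "contact_total"].sum()
    bf = float(bundle / total) if total > 0 else 0.0
    iface = per_helix.loc[per_helix["contact_total"] > min_helix_total, "helix"]
    return InterfaceSummary(per_helix=per_helix, bundle_fraction=bf,
                            interface_helices=sorted(iface))


def helix_pairing_orientation(
    cmap: ContactMap,
    template,
    helix_a: str,
    helix_b: str,
    threshold: float = 0.0,
    anisotropy: float = 2.0,
) -> tuple[str, int]:
    """Classify the contact strand between two helices.

    Principal-axis fit of the above-threshold cells of the (helix_a, helix_b)
    contact block: a strand parallel to the block diagonal means the helices
    pack parallel, normal to it antiparallel.  Returns (verdict, extent in
    residues); verdict "none" when fewer than 3 cells or no clear anisotropy.
    """
    block = cmap.helix_block(template, helix_a, helix_b)
    ii, jj = np.nonzero(block > threshold)
    if len(ii) < 3:
        return "none", 0
    pts = np.column_stack([ii, jj]).astype(float)
    w = block[ii, jj]
    mu = np.average(pts, axis=0, weights=w)
    x = pts - mu
    cov = (x.T * w) @ x / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        ratio = np.inf
    else:
        ratio = evals[1] / evals[0]
    if ratio < anisotropy**2:  # eigenvalues are variances
        return "none", 0
    axis = evecs[:, 1]
    verdict = "parallel" if axis[0] * axis[1] > 0 else "antiparallel"
    proj = x @ axis
    extent = int(round(proj.max() - proj.min())) + 1
    return verdict, extent


def interface_periodicity(
    interface_residues,
    helix_residues,
    period_range: tuple[float, float] = (3.0, 4.5),
    n_periods: int = 151,
) -> tuple[float | None, str]:
    """Dominant period (residues) of the interface indicator along a helix.

    Periodogram of the mean-removed 0/1 indicator, searched over
    ``period_range``.  Returns (period, flag) where flag is "ok",
    "too_few_residues" (< 6 interfacial) or "flat" (no contrast).
    """
    helix_residues = np.sort(np.asarray(helix_residues))
    indicator = np.isin(helix_residues, np.asarray(list(interface_residues)))
    if indicator.sum() < 6:
        return None, "too_few_residues"
    x = indicator.astype(float)
    x -= x.mean()
    if np.allclose(x, 0.0):
        return None, "flat"
    n = np.arange(len(x))
    periods = np.linspace(period_range[0], period_range[1], n_periods)
    power = np.array([
        np.abs(np.sum(x * np.exp(2j * np.pi * n / t))) ** 2 for t in periods
    ])
    return float(periods[int(np.argmax(power))]), "ok"


@dataclass
class BundleScreenResult:
    flags: pd.DataFrame           # replicate, flagged, first_contact, separation, lifetime
    n_replicates: int

    @property
    def count(self) -> int:
        return int(self.flags["flagged"].sum())

    @property
    def percentage(self) -> float:
        """Flagged share of the ensemble, percent, one decimal place."""
        return round(100.0 * self.count / self.n_replicates, 1)


def screen_summary(n_flagged: int, n_replicates: int) -> BundleScreenResult:
    """BundleScreenResult from bare counts (for externally screened data)."""
    flags = pd.DataFrame({
        "replicate": np.arange(n_replicates),
        "flagged": np.arange(n_replicates) < n_flagged,
        "first_contact_us": np.nan,
        "separation_us": np.nan,
        "lifetime_us": np.nan,
    })
    return BundleScreenResult(flags=flags, n_replicates=n_replicates)


def bundle_screen(
    ensemble,
    template,
    bundle_fraction_threshold: float = 0.5,
    persistence: int = 2,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> BundleScreenResult:
    """Flag replicates whose dimer interface is bundle-centered.

    A replicate is flagged if, over at least ``persistence`` consecutive
    stored frames with any contact, the fraction of residue contacts that
    involve a bundle-domain residue on either protomer is >= the threshold.
    first-contact / separation times and the lifetime of the bundle-centered
    episode are reported per replicate.
    """
    res_of_bead = template.residue_index
    bundle_res = set(int(r) for r in template.bundle_residues())
    # cheap pre-filter: only frames whose min bead distance is below the
    # cutoff can hold contacts, so pair enumeration is skipped elsewhere
    mbd = (ensemble.frames
           .pivot(index="replicate", columns="time_us",
                  values="min_bead_distance")
           .to_numpy())
    rows = []
    for r in range(ensemble.n_replicates):
        bf = np.full(ensemble.n_frames, np.nan)
        has_contact = np.zeros(ensemble.n_frames, dtype=bool)
        for fi in np.flatnonzero(mbd[r] < cutoff):
            a, b = ensemble.bead_coords(r, fi)
            pairs = contact_pairs_frame(a, b, res_of_bead, res_of_bead, cutoff)
            if not pairs:
                continue
            has_contact[fi] = True
            n_bundle = sum(1 for i, j in pairs
                           if i in bundle_res or j in bundle_res)
            bf[fi] = n_bundle / len(pairs)
        hot = has_contact & (np.nan_to_num(bf, nan=-1.0)
                             >= bundle_fraction_threshold)
        flagged, start, end = False, np.nan, np.nan
        run = 0
        for fi in range(ensemble.n_frames):
            run = run + 1 if hot[fi] else 0
            if run >= persistence:
                flagged = True
                start = ensemble.times[fi - run + 1]
                break
        if flagged:
            # separation = first later frame with no inter-protomer contact
            start_fi = int(np.searchsorted(ensemble.times, start))
            later = np.flatnonzero(~has_contact[start_fi:])
            end = (ensemble.times[start_fi + later[0]] if len(later)
                   else ensemble.times[-1])
        lifetime = end - start if flagged else np.nan
        rows.append((r, flagged, start, end, lifetime))
    flags = pd.DataFrame(rows, columns=["replicate", "flagged",
                                        "first_contact_us", "separation_us",
                                        "lifetime_us"])
    return BundleScreenResult(flags=flags, n_replicates=ensemble.n_replicates)


def expected_random_encounters(
    n_replicates: int,
    encounter_probability: float,
    angular_fraction: float,
) -> float:
    """Expected bundle-centered contacts under pure random encounters."""
    if not 0.0 <= encounter_probability <= 1.0:
        raise ContactError("encounter_probability must be in [0, 1]")
    if not 0.0 <= angular_fraction <= 1.0:
        raise ContactError("angular_fraction must be in [0, 1]")
    return n_replicates * encounter_probability * angular_fraction
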