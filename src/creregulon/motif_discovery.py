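"""Fixed-width motif discovery by Gibbs site sampling.

The catabolite responsive element (CRE) is a pseudo-palindromic ~16 bp site,
so sampling considers both strands.  Discovery follows the classic site
sampler: hold one sequence out, rebuild the position probability matrix (with
background-proportional pseudocounts) from the remaining sites, and sample the
held-out site's position and strand in proportion to the motif/background
likelihood ratio.  Chains run to a plateau of the alignment log-likelihood
ratio; the best of several independent restarts wins, followed by a phase-
shift polish (the sampler's classic column-shift move) and a recursive
occurrence pass that scans all sequences for additional non-overlapping sites
above an occurrence threshold, so a sequence may contribute zero or several
sites to the final training set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from creregulon.io_formats import reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4

# IUPAC codes for 2-base degeneracy, keyed by frozenset of bases
_IUPAC2 = {
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
}


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0 C=1 G=2 T=3 N=4."""
    try:
        return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r}") from None


@dataclass(frozen=True)
class SiteInstance:
    """One aligned motif occurrence within a region.

    ``offset`` is 0-based within the region; ``strand`` is relative to the
    region ('+' = as given).  ``site_sequence`` is the strand-adjusted site,
    i.e. the reverse complement of the region substring when strand is '-'.
    """

    region_id: str
    offset: int
    strand: str
    width: int
    site_sequence: str

    def __post_init__(self) -> None:
        if len(self.site_sequence) != self.width:
            raise ValueError("site_sequence length != width")


@dataclass
class MotifAlignment:
    sites: list[SiteInstance]
    width: int

    def __post_init__(self) -> None:
        if any(s.width != self.width for s in self.sites):
            raise ValueError("all sites must share the alignment width")

    @property
    def site_sequences(self) -> list[str]:
        return [s.site_sequence for s in self.sites]


@dataclass
class Pwm:
    """Position probability matrix, rows = positions, columns = A,C,G,T."""

    width: int
    probs: np.ndarray  # (width, 4), rows sum to 1
    pseudocount: float
    background: np.ndarray  # (4,), sums to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape != (self.width, 4):
            raise ValueError(f"probs shape {self.probs.shape} != ({self.width}, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    def reverse_complement(self) -> "Pwm":
        return replace(self, probs=self.probs[::-1, ::-1].copy())

    def sample_site(self, rng: np.random.Generator) -> str:
        cols = [rng.choice(4, p=row / row.sum()) for row in self.probs]
        return "".join(BASES[c] for c in cols)


@dataclass(frozen=True)
class MotifComparison:
    offset: int
    orientation: str  # "same" | "revcomp"
    similarity: float  # mean column Pearson r over the overlap
    p_value: float


def uniform_background() -> np.ndarray:
    return np.full(4, 0.25)


def background_from_regions(regions: list[str]) -> np.ndarray:
    """Order-0 background base composition of the input region set."""
    counts = np.zeros(4)
    for seq in regions:
        codes = encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        return uniform_background()
    return counts / counts.sum()


def build_pwm(
    alignment: MotifAlignment | list[str],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> Pwm:
    """Estimate the PWM from aligned sites.

    The total pseudocount mass is distributed across bases in proportion to
    the background composition: probs[i][b] = (count_i(b) + pc·bg_b) / (n + pc).
    """
    seqs = alignment.site_sequences if isinstance(alignment, MotifAlignment) else list(alignment)
    if not seqs:
        raise ValueError("cannot build a PWM from zero sites")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("sites have unequal widths")
    bg = uniform_background() if background is None else np.asarray(background, dtype=float)
    counts = np.zeros((width, 4))
    for s in seqs:
        codes = encode(s)
        for i, c in enumerate(codes):
            if c < 4:
                counts[i, c] += 1
    denom = counts.sum(axis=1, keepdims=True) + pseudocount
    probs = (counts + pseudocount * bg) / denom
    return Pwm(width=width, probs=probs, pseudocount=pseudocount, background=bg)


def consensus(pwm: Pwm, single_cut: float = 0.6, pair_cut: float = 0.8) -> str:
    """Reduce a PWM to an IUPAC consensus string.

    Per column: the single most probable base if its probability ≥
    ``single_cut``; else the 2-base IUPAC code (W, S, R, Y, K, M) if the top
    two sum to ≥ ``pair_cut``; else N.
    """
    letters = []
    for row in pwm.probs:
        order = np.argsort(row)[::-1]
        if row[order[0]] >= single_cut:
            letters.append(BASES[order[0]])
        elif row[order[0]] + row[order[1]] >= pair_cut:
            letters.append(_IUPAC2[frozenset(BASES[order[0]] + BASES[order[1]])])
        else:
            letters.append("N")
    return "".join(letters)


def information_content(
    pwm: Pwm, background: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Per-column and total information content in bits.

    Relative entropy of each column against the background; with the uniform
    background this reduces to 2 + Σ_b p log2 p per column.
    """
    bg = pwm.background if background is None else np.asarray(background, dtype=float)
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / bg), 0.0)
    per_column = terms.sum(axis=1)
    return per_column, float(per_column.sum())


def _window_scores(codes: np.ndarray, log_odds: np.ndarray, width: int) -> np.ndarray:
    """Log-odds score of every window of ``codes`` (N contributes 0)."""
    n = len(codes) - width + 1
    if n <= 0:
        return np.zeros(0)
    lo = np.hstack([log_odds, np.zeros((width, 1))])  # column 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(codes, width)
    return lo[np.arange(width), windows].sum(axis=1)


def _log_odds(pwm_probs: np.ndarray, background: np.ndarray) -> np.ndarray:
    return np.log2(pwm_probs / background)


class _SamplerState:
    """One Gibbs chain over encoded regions, exactly one site per sequence."""

    def __init__(
        self,
        codes_fwd: list[np.ndarray],
        codes_rev: list[np.ndarray],
        width: int,
        background: np.ndarray,
        pseudocount: float,
        rng: np.random.Generator,
    ):
        self.fwd = codes_fwd
        self.rev = codes_rev
        self.width = width
        self.bg = background
        self.pc = pseudocount
        self.rng = rng
        self.n = len(codes_fwd)
        self.offsets = np.array(
            [rng.integers(0, len(c) - width + 1) for c in codes_fwd]
        )
        self.strands = rng.integers(0, 2, size=self.n)  # 0 = '+', 1 = '-'

    def _site_codes(self, i: int) -> np.ndarray:
        codes = self.fwd[i] if self.strands[i] == 0 else self.rev[i]
        off = self.offsets[i]
        if self.strands[i] == 1:
            off = len(codes) - self.width - self.offsets[i]
        return codes[off : off + self.width]

    def _site_counts(self, i: int) -> np.ndarray:
        counts = np.zeros((self.width, 4))
        site = self._site_codes(i)
        valid = site < 4
        counts[np.arange(self.width)[valid], site[valid]] = 1
        return counts

    def _total_counts(self) -> np.ndarray:
        counts = np.zeros((self.width, 4))
        for i in range(self.n):
            counts += self._site_counts(i)
        return counts

    def sweep(self, greedy: bool = False) -> bool:
        """One hold-one-out pass; ``greedy`` takes the argmax instead of sampling.

        Returns True if any site moved (used for greedy-polish convergence).
        """
        total = self._total_counts()
        order = self.rng.permutation(self.n)
        moved = False
        for i in order:
            total -= self._site_counts(i)
            counts = total
            probs = (counts + self.pc * self.bg) / (
                counts.sum(axis=1, keepdims=True) + self.pc
            )
            lo = _log_odds(probs, self.bg)
            s_fwd = _window_scores(self.fwd[i], lo, self.width)
            s_rev = _window_scores(self.rev[i], lo, self.width)
            # map reverse-strand windows back to forward-coordinate offsets
            s_rev = s_rev[::-1]
            scores = np.concatenate([s_fwd, s_rev])
            if greedy:
                choice = int(np.argmax(scores))
            else:
                weights = np.exp2(scores - scores.max())
                weights /= weights.sum()
                choice = self.rng.choice(len(weights), p=weights)
            old = (self.offsets[i], self.strands[i])
            if choice < len(s_fwd):
                self.offsets[i], self.strands[i] = choice, 0
            else:
                self.offsets[i], self.strands[i] = choice - len(s_fwd), 1
            moved = moved or (self.offsets[i], self.strands[i]) != old
            total += self._site_counts(i)
        return moved

    def score(self) -> float:
        """Alignment log-likelihood ratio vs background, in bits."""
        counts = self._total_counts()
        probs = (counts + self.pc * self.bg) / (
            counts.sum(axis=1, keepdims=True) + self.pc
        )
        lo = np.hstack([_log_odds(probs, self.bg), np.zeros((self.width, 1))])
        total = 0.0
        for i in range(self.n):
            site = self._site_codes(i)
            total += lo[np.arange(self.width), site].sum()
        return float(total)

    def _shifted(self, shift: int) -> np.ndarray | None:
        """Forward-coordinate offsets for a common motif-space shift (strand-aware)."""
        delta = np.where(self.strands == 0, shift, -shift)
        shifted = self.offsets + delta
        ok = all(
            0 <= shifted[i] <= len(self.fwd[i]) - self.width for i in range(self.n)
        )
        return shifted if ok else None

    def try_shift(self) -> None:
        """Phase-shift polish: slide the whole alignment if a shift scores better."""
        best_shift, best_score = 0, self.score()
        saved = self.offsets.copy()
        for shift in (-2, -1, 1, 2):
            shifted = self._shifted(shift)
            if shifted is None:
                continue
            self.offsets = shifted
            s = self.score()
            if s > best_score:
                best_shift, best_score = shift, s
            self.offsets = saved
        shifted = self._shifted(best_shift) if best_shift else None
        if shifted is not None:
            self.offsets = shifted


def gibbs_sample_motif(
    regions: list[str],
    width: int = 16,
    both_strands: bool = True,
    restarts: int = 8,
    max_iter: int = 300,
    seed: int = 0,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    plateau: int = 25,
    region_ids: list[str] | None = None,
) -> tuple[MotifAlignment, Pwm]:
    """Discover one fixed-width motif across regions by Gibbs site sampling.

    Runs ``restarts`` independent chains, each iterating hold-one-out sweeps
    until the best alignment score has not improved for ``plateau`` sweeps (or
    ``max_iter`` is reached), and returns the best-scoring alignment overall
    after a phase-shift polish.  The background is order-0, estimated from the
    input regions unless given.  Deterministic for a fixed seed.
    """
    if len(regions) < 3:
        raise ValueError("need at least 3 regions for motif discovery")
    for idx, r in enumerate(regions):
        if len(r) < width:
            rid = region_ids[idx] if region_ids else f"region {idx}"
            raise ValueError(f"{rid} is shorter ({len(r)}) than the motif width ({width})")
    ids = region_ids if region_ids is not None else [f"region_{i}" for i in range(len(regions))]
    bg = background_from_regions(regions) if background is None else np.asarray(background, float)
    bg = np.clip(bg, 1e-9, None)
    bg = bg / bg.sum()
    codes_fwd = [encode(r) for r in regions]
    if both_strands:
        codes_rev = [encode(reverse_complement(r)) for r in regions]
    else:
        # single-strand mode: the 'reverse' codes are all-N, scoring 0 everywhere,
        # so reverse windows are never competitive
        codes_rev = [np.full(len(c), 4, dtype=np.int8) for c in codes_fwd]
    rng = np.random.default_rng(seed)
    best_state: _SamplerState | None = None
    best_score = -np.inf
    for _ in range(restarts):
        chain_rng = np.random.default_rng(rng.integers(0, 2**31))
        state = _SamplerState(codes_fwd, codes_rev, width, bg, pseudocount, chain_rng)
        chain_best, since_improved = -np.inf, 0
        chain_best_snapshot = (state.offsets.copy(), state.strands.copy())
        for _ in range(max_iter):
            state.sweep()
            s = state.score()
            if s > chain_best + 1e-9:
                chain_best, since_improved = s, 0
                chain_best_snapshot = (state.offsets.copy(), state.strands.copy())
            else:
                since_improved += 1
                if since_improved >= plateau:
                    break
        state.offsets, state.strands = chain_best_snapshot
        # zero-temperature polish: hill-climb to the local MAP state
        for _ in range(10):
            if not state.sweep(greedy=True):
                break
        state.try_shift()
        s = state.score()
        if s > best_score:
            best_score, best_state = s, state
    assert best_state is not None
    sites = []
    for i in range(best_state.n):
        strand = "+" if best_state.strands[i] == 0 else "-"
        off = int(best_state.offsets[i])
        site_codes = best_state._site_codes(i)
        site_seq = "".join("ACGTN"[c] for c in site_codes)
        sites.append(
            SiteInstance(
                region_id=ids[i], offset=off, strand=strand, width=width, site_sequence=site_seq
            )
        )
    alignment = MotifAlignment(sites=sites, width=width)
    pwm = build_pwm(alignment, pseudocount=pseudocount, background=bg)
    return alignment, pwm


def recursive_pass(
    regions: list[str],
    pwm: Pwm,
    mask_found: bool = True,
    ic_floor: float = 8.0,
    min_score: float | None = None,
    alignment: MotifAlignment | None = None,
    region_ids: list[str] | None = None,
    max_rounds: int = 20,
) -> MotifAlignment:
    """Converge-then-mask-then-rescan: find zero-or-more sites per sequence.

    Scans every region on both strands for additional non-overlapping
    occurrences with log-odds score above ``min_score`` (greedy by score),
    masks them, rebuilds the PWM from the enlarged site set, and repeats until
    no new occurrence qualifies.  The union over passes is the training set.

    ``min_score`` defaults to half the motif's information content: the
    expected score of a true site equals the IC while background windows score
    far below zero, so the midpoint separates the two populations.  A fixed
    low threshold (e.g. 0 bits) admits a trickle of background windows whose
    inclusion degrades the PWM and lets ever more background qualify — a
    runaway that contaminates the training set.  If the PWM's total
    information content is below ``ic_floor`` bits the motif is too diffuse to
    extrapolate and the input alignment is returned unchanged.
    """
    width = pwm.width
    ids = region_ids if region_ids is not None else [f"region_{i}" for i in range(len(regions))]
    sites: list[SiteInstance] = list(alignment.sites) if alignment else []
    _, total_ic = information_content(pwm)
    if total_ic < ic_floor:
        return MotifAlignment(sites=sites, width=width)
    if min_score is None:
        min_score = total_ic / 2.0
    occupied: dict[str, set[int]] = {rid: set() for rid in ids}
    for s in sites:
        if s.region_id in occupied:
            occupied[s.region_id].update(range(s.offset, s.offset + width))
    current_pwm = pwm
    for _ in range(max_rounds):
        lo = _log_odds(current_pwm.probs, current_pwm.background)
        candidates: list[tuple[float, int, int, str]] = []
        for i, region in enumerate(regions):
            codes = encode(region)
            s_fwd = _window_scores(codes, lo, width)
            s_rev = _window_scores(encode(reverse_complement(region)), lo, width)[::-1]
            for off in range(len(s_fwd)):
                if occupied[ids[i]] & set(range(off, off + width)):
                    continue
                if s_fwd[off] > min_score or s_rev[off] > min_score:
                    if s_fwd[off] >= s_rev[off]:
                        candidates.append((float(s_fwd[off]), i, off, "+"))
                    else:
                        candidates.append((float(s_rev[off]), i, off, "-"))
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        added = []
        for score, i, off, strand in candidates:
            if occupied[ids[i]] & set(range(off, off + width)):
                continue
            window = regions[i][off : off + width]
            site_seq = window if strand == "+" else reverse_complement(window)
            added.append(
                SiteInstance(
                    region_id=ids[i], offset=off, strand=strand, width=width, site_sequence=site_seq
                )
            )
            if mask_found:
                occupied[ids[i]].update(range(off, off + width))
        if not added:
            break
        sites.extend(added)
        current_pwm = build_pwm(
            MotifAlignment(sites=sites, width=width),
            pseudocount=current_pwm.pseudocount,
            background=current_pwm.background,
        )
        if not mask_found:
            break
    return MotifAlignment(sites=sites, width=width)


def _column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r between two 4-vectors; 0 when either is constant."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _best_alignment_similarity(
    q: np.ndarray, r: np.ndarray, min_overlap: int
) -> tuple[float, int, str] | None:
    """Best mean column-Pearson similarity of q against r over offsets/orientations."""
    best: tuple[float, int, str] | None = None
    for orientation in ("same", "revcomp"):
        ref = r if orientation == "same" else r[::-1, ::-1]
        wq, wr = q.shape[0], ref.shape[0]
        for offset in range(-(wq - min_overlap), wr - min_overlap + 1):
            qs = max(0, -offset)
            rs = max(0, offset)
            ov = min(wq - qs, wr - rs)
            if ov < min_overlap:
                continue
            sims = [
                _column_correlation(q[qs + k], ref[rs + k]) for k in range(ov)
            ]
            sim = float(np.mean(sims))
            if best is None or sim > best[0]:
                best = (sim, offset, orientation)
    return best


def compare_motifs(
    query: Pwm,
    reference: Pwm,
    min_overlap: int = 8,
    n_null: int = 999,
    seed: int = 0,
) -> MotifComparison:
    """Compare two PWMs by best mean column-Pearson correlation.

    All relative offsets with ≥ ``min_overlap`` overlapping columns are tried
    in both orientations (reverse complement = columns reversed, A↔T, C↔G).
    The p-value is the add-one-corrected Monte-Carlo fraction of column-
    shuffled queries whose best similarity reaches the observed one.
    """
    if query.width < min_overlap or reference.width < min_overlap:
        raise ValueError("motif shorter than min_overlap: no alignment possible")
    observed = _best_alignment_similarity(query.probs, reference.probs, min_overlap)
    assert observed is not None
    sim, offset, orientation = observed
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_null):
        perm = rng.permutation(query.width)
        null = _best_alignment_similarity(query.probs[perm], reference.probs, min_overlap)
        if null is not None and null[0] >= sim:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_null)
    return MotifComparison(offset=offset, orientation=orientation, similarity=sim, p_value=p_value)


def write_pwm_meme(pwm: Pwm, path, name: str = "CRE") -> None:
    """Serialize a PWM in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            + " ".join(f"{b} {f:.6f}" for b, f in zip(BASES, pwm.background))
            + "\n\n"
        )
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width}\n")
        for row in pwm.probs:
            fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
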