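"""Template-constrained folding and classification of (truncated) mt tRNAs.

Metazoan mitochondrial tRNAs are folded here against the cloverleaf template
rather than thermodynamically: an acceptor stem built from terminal
complementarity, an anticodon arm anchored on a 7-nt loop, and D- and T-arms
searched in the regions left between them.  An arm is *present* iff a hairpin
with at least ``min_arm_pairs`` Watson-Crick/GU pairs (at most one internal
mismatch) and a 3-9 nt loop fits its region; otherwise the region is recorded
as a replacement loop.  A tRNA with both D- and T-arms is a cloverleaf;
missing arms give the D-armless, T-armless and armless classes that dominate
acariform mitochondria.

Mismatches found inside stems are recorded and penalized in the score but do
not, on their own, flip an arm to absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .vocab import ANTICODON_FAMILY, FAMILY_AA

#: Watson-Crick plus GU wobble, DNA alphabet (U normalized to T)
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

MIN_LEN, MAX_LEN = 40, 100


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


@dataclass(frozen=True)
class FoldingThresholds:
    """Tunable template constraints (defaults documented in the methods note)."""

    min_arm_pairs: int = 2       # stem pairs required for an arm to be present
    max_arm_mismatches: int = 1  # tolerated inside a D/T stem
    loop_min: int = 3
    loop_max: int = 9
    acceptor_len: int = 7
    acceptor_max_mismatches: int = 2
    anticodon_stem_max: int = 5
    d_stem_max: int = 4
    t_stem_max: int = 5
    pair_reward: int = 2
    mismatch_penalty: int = 1


DEFAULT_THRESHOLDS = FoldingThresholds()


@dataclass(frozen=True)
class Arm:
    present: bool
    stem_pairs: int = 0
    mismatches: int = 0
    loop_len: int | None = None
    replacement_len: int | None = None  # length of the loop replacing a lost arm
    region: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class TrnaStructure:
    sequence: str
    anticodon: str
    anticodon_loop_start: int
    pairs: tuple[tuple[int, int], ...]   # 0-based paired positions, 5' index first
    acceptor: Arm
    d_arm: Arm
    anticodon_arm: Arm
    t_arm: Arm
    total_score: int

    def __post_init__(self):
        used = [i for p in self.pairs for i in p]
        if len(used) != len(set(used)):
            raise ValueError("a base is paired twice")
        for i, j in self.pairs:
            if not can_pair(self.sequence[i], self.sequence[j]):
                raise ValueError(f"non-canonical pair at ({i},{j})")

    @property
    def classification(self) -> str:
        return classify(self)

    @property
    def amino_acid(self) -> str | None:
        fam = ANTICODON_FAMILY.get(self.anticodon)
        return FAMILY_AA[fam] if fam else None

    @property
    def family(self) -> str | None:
        return ANTICODON_FAMILY.get(self.anticodon)

    def dot_bracket(self) -> str:
        db = ["."] * len(self.sequence)
        for i, j in self.pairs:
            db[i], db[j] = "(", ")"
        return "".join(db)


class FoldError(ValueError):
    """The sequence cannot accommodate the anticodon arm template."""


@dataclass(frozen=True)
class AnticodonCandidate:
    loop_start: int          # index of the 7-nt anticodon loop
    anticodon: str
    stem_pairs: int

    @property
    def anticodon_start(self) -> int:
        return self.loop_start + 2


def locate_anticodon(seq: str, expected: str | None = None,
                     thresholds: FoldingThresholds = DEFAULT_THRESHOLDS) -> list[AnticodonCandidate]:
    """Candidate anticodon positions: centers of 7-nt loops closed by a stem
    of >= 2 WC/GU pairs, ranked by stem strength then centrality; candidates
    matching ``expected`` (if given) rank first.  Empty list if none."""
    s = _norm(seq)
    n = len(s)
    if not MIN_LEN <= n <= MAX_LEN:
        raise ValueError(f"tRNA length {n} outside [{MIN_LEN}, {MAX_LEN}]")
    exp = _norm(expected) if expected else None
    cands = []
    for loop_start in range(2, n - 7 - 1):
        stem = 0
        for k in range(1, thresholds.anticodon_stem_max + 1):
            i, j = loop_start - k, loop_start + 6 + k
            if i < 0 or j >= n or not can_pair(s[i], s[j]):
                break
            stem += 1
        if stem >= 2:
            cands.append(AnticodonCandidate(loop_start, s[loop_start + 2:loop_start + 5], stem))
    center = (n - 7) / 2
    cands.sort(key=lambda c: (0 if (exp and c.anticodon == exp) else 1,
                              -c.stem_pairs, abs(c.loop_start - center), c.loop_start))
    return cands


def _tolerant_stem(s: str, get_i, get_j, max_len: int, max_mm: int) -> tuple[int, int, list[tuple[int, int]]]:
    """Extend a stem outward position by position, tolerating mismatches.

    Returns (consumed positions, mismatches, paired index list)."""
    status = []  # True = paired at step k
    pairs = []
    mm = 0
    for k in range(max_len):
        i, j = get_i(k), get_j(k)
        if i is None or j is None:
            break
        if can_pair(s[i], s[j]):
            status.append(True)
            pairs.append((min(i, j), max(i, j)))
        else:
            if mm + 1 > max_mm:
                break
            mm += 1
            status.append(False)
    # the stem ends at its outermost pair; mismatches beyond it are not stem
    while status and not status[-1]:
        status.pop()
    consumed = len(status)
    return consumed, status.count(False), pairs


def _search_hairpin(s: str, lo: int, hi: int, max_stem: int,
                    th: FoldingThresholds) -> tuple | None:
    """Best hairpin inside s[lo:hi]: maximal stem, then fewest mismatches,
    then 5'-most.  Returns (stem_total, mismatches, offset, loop_len, pairs)."""
    best = None
    region_len = hi - lo
    for stem in range(min(max_stem, (region_len - th.loop_min) // 2), th.min_arm_pairs - 1, -1):
        for off in range(0, region_len - 2 * stem - th.loop_min + 1):
            for loop in range(th.loop_min, min(th.loop_max, region_len - 2 * stem - off) + 1):
                pairs, mm = [], 0
                for k in range(stem):
                    i = lo + off + k
                    j = lo + off + 2 * stem + loop - 1 - k
                    if can_pair(s[i], s[j]):
                        pairs.append((i, j))
                    else:
                        mm += 1
                if len(pairs) >= th.min_arm_pairs and mm <= th.max_arm_mismatches:
                    cand = (stem, mm, off, loop, tuple(pairs))
                    if best is None or (-cand[0], cand[1], cand[2]) < (-best[0], best[1], best[2]):
                        best = cand
        if best is not None:
            break  # stems are tried longest-first
    return best


def fold_trna(seq: str, anticodon_loop_start: int,
              thresholds: FoldingThresholds = DEFAULT_THRESHOLDS) -> TrnaStructure:
    """Fold under the cloverleaf template given the anticodon loop position."""
    s = _norm(seq)
    n = len(s)
    th = thresholds
    if not MIN_LEN <= n <= MAX_LEN:
        raise ValueError(f"tRNA length {n} outside [{MIN_LEN}, {MAX_LEN}]")
    p = anticodon_loop_start
    if p < 2 or p + 7 + 2 > n:
        raise FoldError(f"anticodon loop at {p} leaves no room for its stem")

    # anticodon stem: outward from the loop
    ac_len, ac_mm, ac_pairs = _tolerant_stem(
        s, lambda k: p - 1 - k if p - 1 - k >= 0 else None,
        lambda k: p + 7 + k if p + 7 + k < n else None,
        th.anticodon_stem_max, 1)
    if len(ac_pairs) < 2:
        raise FoldError("anticodon stem needs at least two pairs")

    # acceptor stem from terminal complementarity
    acc_len, acc_mm, acc_pairs = _tolerant_stem(
        s, lambda k: k, lambda k: n - 1 - k,
        th.acceptor_len, th.acceptor_max_mismatches)
    acceptor = Arm(present=True, stem_pairs=len(acc_pairs), mismatches=acc_mm,
                   region=(0, acc_len))

    d_lo, d_hi = acc_len, p - ac_len
    t_lo, t_hi = p + 7 + ac_len, n - acc_len

    def arm(lo: int, hi: int, max_stem: int) -> tuple[Arm, tuple]:
        if hi - lo < 2 * th.min_arm_pairs + th.loop_min:
            return Arm(False, replacement_len=max(hi - lo, 0), region=(lo, hi)), ()
        hit = _search_hairpin(s, lo, hi, max_stem, th)
        if hit is None:
            return Arm(False, replacement_len=hi - lo, region=(lo, hi)), ()
        stem, mm, off, loop, pairs = hit
        return Arm(True, stem_pairs=len(pairs), mismatches=mm, loop_len=loop,
                   region=(lo, hi)), pairs

    d_arm, d_pairs = arm(d_lo, d_hi, th.d_stem_max)
    t_arm, t_pairs = arm(t_lo, t_hi, th.t_stem_max)
    anticodon_arm = Arm(True, stem_pairs=len(ac_pairs), mismatches=ac_mm,
                        loop_len=7, region=(p - ac_len, p + 7 + ac_len))

    all_pairs = tuple(sorted(acc_pairs + ac_pairs + list(d_pairs) + list(t_pairs)))
    score = th.pair_reward * len(all_pairs) - th.mismatch_penalty * (
        acc_mm + ac_mm + d_arm.mismatches + t_arm.mismatches)
    return TrnaStructure(
        sequence=s, anticodon=s[p + 2:p + 5], anticodon_loop_start=p,
        pairs=all_pairs, acceptor=acceptor, d_arm=d_arm,
        anticodon_arm=anticodon_arm, t_arm=t_arm, total_score=score)


def fold_best(seq: str, expected_anticodon: str | None = None,
              thresholds: FoldingThresholds = DEFAULT_THRESHOLDS) -> TrnaStructure:
    """Fold at the top-ranked anticodon candidate."""
    cands = locate_anticodon(seq, expected_anticodon, thresholds)
    if not cands:
        raise FoldError("no anticodon candidate found")
    last_err: Exception | None = None
    for c in cands:
        try:
            return fold_trna(seq, c.loop_start, thresholds)
        except FoldError as e:  # pragma: no cover - candidates rarely all fail
            last_err = e
    raise last_err  # type: ignore[misc]


CLASSES = ("cloverleaf", "D-armless", "T-armless", "armless")


def classify(structure: TrnaStructure) -> str:
    """Cloverleaf iff both D- and T-arms are present."""
    d, t = structure.d_arm.present, structure.t_arm.present
    if d and t:
        return "cloverleaf"
    if t:
        return "D-armless"
    if d:
        return "T-armless"
    return "armless"


@dataclass
class TruncationSummary:
    """Per-genome class counts and cross-genome arm-loss patterns."""

    counts: dict[str, dict[str, int]]            # genome -> class -> count
    family_pattern: dict[str, dict[str, str]]    # family -> genome -> class
    shared_loss: dict[str, list[str]]            # arm ("D"/"T") -> families lacking it everywhere
    size_range: tuple[int, int]

    @property
    def n_atypical(self) -> dict[str, int]:
        return {g: sum(v for k, v in c.items() if k != "cloverleaf")
                for g, c in self.counts.items()}


def truncation_summary(per_genome: dict[str, dict[str, TrnaStructure]]) -> TruncationSummary:
    """Summarize classifications across genomes.

    ``per_genome`` maps genome label -> tRNA family -> folded structure.
    A family is a shared loss for an arm when that arm is absent in every
    genome in which the family was folded.
    """
    if not per_genome:
        raise ValueError("no genomes supplied")
    counts: dict[str, dict[str, int]] = {}
    family_pattern: dict[str, dict[str, str]] = {}
    sizes = []
    for genome, fams in per_genome.items():
        counts[genome] = {c: 0 for c in CLASSES}
        for fam, st in fams.items():
            cls = st.classification
            counts[genome][cls] += 1
            family_pattern.setdefault(fam, {})[genome] = cls
            sizes.append(len(st.sequence))
    shared_loss: dict[str, list[str]] = {"D": [], "T": []}
    for fam, pat in sorted(family_pattern.items()):
        classes = set(pat.values())
        if classes <= {"D-armless", "armless"}:
            shared_loss["D"].append(fam)
        if classes <= {"T-armless", "armless"}:
            shared_loss["T"].append(fam)
    return TruncationSummary(counts=counts, family_pattern=family_pattern,
                             shared_loss=shared_loss,
                             size_range=(min(sizes), max(sizes)))


def read_trna_fasta(path) -> list[tuple[str, str]]:
    """Read tRNA records; the first header token is the family label."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id.split("|")[0], str(rec.seq)))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out
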