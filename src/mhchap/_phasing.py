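"""Co-segregation engine for presence-set haplotype inference.

Shared by STR haplotyping and A-B haplotype phasing.  The problem: each
animal's observation is a *presence set* of items (allele names, or
(marker, length) tokens); the truth is that every animal carries two
haplotypes (item sets) whose union is the observation, and every
non-founder received one haplotype of its dam and one of a candidate
sire, unchanged.  Copy number varies freely, dosage is unobservable, and
the catalogue of distinct haplotypes should be as small as possible --
the same parsimony a human analyst applies when deducing haplotypes from
families.

The engine is a constraint solver:

1. every animal owns two *slots* (maternal/paternal); transmission ties a
   child slot to one of the parent's slots, so decided slots merge into
   equivalence classes (union-find), each class being one transmitted
   haplotype with an interval constraint ``lower <= H <= upper``;
2. interval propagation: ``upper`` is the intersection of the carriers'
   observations; an item of the observation missing from the partner
   slot's upper bound is forced into ``lower``; transmissions and sire
   choices with a single consistent option are fixed;
3. exhaustive search over the remaining transmission choices (depth-first
   with propagation, deterministic ordering, node cap);
4. per complete linkage state, classes are greedily-exactly merged into a
   minimal catalogue (exact set-partition search per compatibility
   component up to a size cap), and left-over ambiguous items are placed
   deterministically and flagged.

Animals whose observation cannot be explained are flagged, never forced;
an infeasible family raises :class:`MendelianError` naming the family,
unless ``allow_detach`` is set, in which case the offending transmission
is detached and recorded as a recombination suspect.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Hashable, Optional, Sequence

from .model import MendelianError, PedigreeRecord

Item = Hashable
Slot = tuple[str, str]           # (animal_id, "m" | "p")

_NODE_CAP = 20000
_STATE_CAP = 256
_PARTITION_CAP = 9               # max component size for exact partition search


@dataclass
class Meiosis:
    child_slot: Slot
    options: tuple[tuple[Optional[str], Slot], ...]   # (sire_id or None, parent slot)
    decided: bool = False
    chosen_sire: Optional[str] = None
    detached: bool = False


@dataclass
class PhasingSolution:
    catalogue: list[frozenset]                       # canonical order
    assignments: dict[str, Optional[tuple[int, int]]]  # animal -> (mat, pat) index
    flagged: dict[str, str]                          # animal -> reason
    sire_used: dict[str, Optional[str]]
    ambiguous_sires: set[str]
    recomb_suspects: list[tuple[str, str]]           # (animal, which slot)
    n_optimal: int = 1                               # co-optimal catalogues seen


class _State:
    __slots__ = ("parent", "lower", "upper", "meioses", "suspects")

    def __init__(self) -> None:
        self.parent: dict[Slot, Slot] = {}
        self.lower: dict[Slot, set] = {}
        self.upper: dict[Slot, set] = {}
        self.meioses: list[Meiosis] = []
        self.suspects: list[tuple[str, str]] = []

    def clone(self) -> "_State":
        st = _State()
        st.parent = dict(self.parent)
        st.lower = {k: set(v) for k, v in self.lower.items()}
        st.upper = {k: set(v) for k, v in self.upper.items()}
        st.meioses = [Meiosis(m.child_slot, m.options, m.decided, m.chosen_sire,
                              m.detached) for m in self.meioses]
        st.suspects = list(self.suspects)
        return st

    def find(self, s: Slot) -> Slot:
        p = self.parent
        while p[s] != s:
            p[s] = p[p[s]]
            s = p[s]
        return s


class Phaser:
    def __init__(self, observations: dict[str, frozenset],
                 pedigree: Sequence[PedigreeRecord],
                 partial_valid: Optional[Callable[[frozenset], bool]] = None,
                 allow_detach: bool = False):
        self.obs = {a: frozenset(v) for a, v in observations.items()}
        self.pedigree = {r.animal_id: r for r in pedigree}
        self.animals = sorted(a for a in self.obs if a in self.pedigree)
        self.partial_valid = partial_valid or (lambda s: True)
        self.allow_detach = allow_detach
        self._nodes = 0

    # -- state construction -------------------------------------------------

    def _init_state(self) -> _State:
        st = _State()
        for a in self.animals:
            for w in ("m", "p"):
                s = (a, w)
                st.parent[s] = s
                st.lower[s] = set()
                st.upper[s] = set(self.obs[a])
        for a in self.animals:
            rec = self.pedigree[a]
            if rec.dam_id and rec.dam_id in self.obs:
                st.meioses.append(Meiosis(
                    child_slot=(a, "m"),
                    options=((None, (rec.dam_id, "m")), (None, (rec.dam_id, "p")))))
            sire_opts = tuple((s, (s, w)) for s in rec.sire_ids
                              if s in self.obs for w in ("m", "p"))
            if sire_opts:
                st.meioses.append(Meiosis(child_slot=(a, "p"), options=sire_opts))
        return st

    # -- propagation --------------------------------------------------------

    def _compatible(self, st: _State, r1: Slot, r2: Slot) -> bool:
        if r1 == r2:
            return True
        lo = st.lower[r1] | st.lower[r2]
        return (lo <= st.upper[r1] and lo <= st.upper[r2]
                and self.partial_valid(frozenset(lo)))

    def _merge(self, st: _State, r1: Slot, r2: Slot) -> bool:
        r1, r2 = st.find(r1), st.find(r2)
        if r1 == r2:
            return True
        if r2 < r1:
            r1, r2 = r2, r1
        lo = st.lower[r1] | st.lower[r2]
        up = st.upper[r1] & st.upper[r2]
        if not lo <= up or not self.partial_valid(frozenset(lo)):
            return False
        st.parent[r2] = r1
        st.lower[r1] = lo
        st.upper[r1] = up
        return True

    def _propagate(self, st: _State) -> bool:
        changed = True
        while changed:
            changed = False
            for a in self.animals:
                rm, rp = st.find((a, "m")), st.find((a, "p"))
                u = self.obs[a]
                if rm == rp:
                    # homozygous class: H union H = obs forces H == obs
                    if not u <= st.lower[rm]:
                        st.lower[rm] |= u
                        if (not st.lower[rm] <= st.upper[rm]
                                or not self.partial_valid(frozenset(st.lower[rm]))):
                            return False
                        changed = True
                    continue
                for rx, ry in ((rm, rp), (rp, rm)):
                    forced = u - st.upper[ry]
                    if not forced <= st.lower[rx]:
                        st.lower[rx] |= forced
                        if (not st.lower[rx] <= st.upper[rx]
                                or not self.partial_valid(frozenset(st.lower[rx]))):
                            return False
                        changed = True
            for m in st.meioses:
                if m.decided or m.detached:
                    continue
                rc = st.find(m.child_slot)
                ok = [(sire, st.find(slot)) for sire, slot in m.options
                      if self._compatible(st, rc, st.find(slot))]
                roots = {r for _, r in ok}
                if not ok:
                    if self.allow_detach:
                        m.detached = True
                        st.suspects.append(m.child_slot)
                        changed = True
                        continue
                    return False
                if len(roots) == 1:
                    sires = {s for s, _ in ok}
                    if not self._merge(st, rc, ok[0][1]):
                        return False
                    m.decided = True
                    m.chosen_sire = ok[0][0] if len(sires) == 1 else None
                    changed = True
        return True

    # -- search over undecided transmissions --------------------------------

    def _search(self, st: _State) -> list[_State]:
        complete: list[_State] = []

        def undecided(s: _State) -> Optional[Meiosis]:
            for m in s.meioses:
                if not m.decided and not m.detached:
                    return m
            return None

        def dfs(s: _State) -> None:
            self._nodes += 1
            if self._nodes > _NODE_CAP or len(complete) >= _STATE_CAP:
                return
            m = undecided(s)
            if m is None:
                complete.append(s)
                return
            rc = s.find(m.child_slot)
            opts = [(sire, s.find(slot)) for sire, slot in m.options
                    if self._compatible(s, rc, s.find(slot))]
            # deduplicate options that merged to the same root
            seen: set[Slot] = set()
            uniq = []
            for sire, r in sorted(opts, key=lambda x: (str(x[0]), x[1])):
                if r not in seen:
                    seen.add(r)
                    uniq.append((sire, r))
            # interchangeable fully-determined options: take the first only
            if (len(uniq) > 1 and
                    all(s.lower[r] == s.upper[r] for _, r in uniq) and
                    len({frozenset(s.lower[r]) for _, r in uniq}) == 1 and
                    len({sire for sire, _ in uniq}) == 1):
                uniq = uniq[:1]
            if not uniq:
                if self.allow_detach:
                    s2 = s.clone()
                    for mm in s2.meioses:
                        if mm.child_slot == m.child_slot:
                            mm.detached = True
                    s2.suspects.append(m.child_slot)
                    if self._propagate(s2):
                        dfs(s2)
                return
            for sire, r in uniq:
                s2 = s.clone()
                mm = next(x for x in s2.meioses if x.child_slot == m.child_slot)
                if not self._merge(s2, s2.find(mm.child_slot), s2.find(r)):
                    continue
                mm.decided = True
                mm.chosen_sire = sire
                if self._propagate(s2):
                    dfs(s2)

        dfs(st)
        return complete

    # -- catalogue construction from a complete state ------------------------

    def _finalize(self, st: _State):
        roots = sorted({st.find((a, w)) for a in self.animals for w in ("m", "p")})
        must = {r: frozenset(st.lower[r]) for r in roots}
        cap = {r: frozenset(st.upper[r]) for r in roots}

        # compatibility graph for cross-family merging
        adj: dict[Slot, set[Slot]] = {r: set() for r in roots}
        for r1, r2 in itertools.combinations(roots, 2):
            u = must[r1] | must[r2]
            if (u <= cap[r1] and u <= cap[r2] and self.partial_valid(u)):
                adj[r1].add(r2)
                adj[r2].add(r1)

        # connected components
        comp_of: dict[Slot, int] = {}
        comps: list[list[Slot]] = []
        for r in roots:
            if r in comp_of:
                continue
            stack, comp = [r], []
            comp_of[r] = len(comps)
            while stack:
                x = stack.pop()
                comp.append(x)
                for y in adj[x]:
                    if y not in comp_of:
                        comp_of[y] = len(comps)
                        stack.append(y)
            comps.append(sorted(comp))

        slot_roots = {a: (st.find((a, "m")), st.find((a, "p")))
                      for a in self.animals}

        def block_ok(block: tuple[Slot, ...]) -> Optional[frozenset]:
            u = frozenset().union(*(must[r] for r in block))
            bset = set(block)
            blockcap = None
            for r in block:
                if not u <= cap[r]:
                    return None
                blockcap = cap[r] if blockcap is None else blockcap & cap[r]
            if not self.partial_valid(u):
                return None
            # an animal homozygous for this block must be fully coverable by it
            for a, (rm, rp) in slot_roots.items():
                if rm in bset and rp in bset and not self.obs[a] <= blockcap:
                    return None
            return u

        group_of: dict[Slot, int] = {}
        group_content: list[frozenset] = []

        for comp in comps:
            if len(comp) <= _PARTITION_CAP:
                best: Optional[list[tuple[tuple[Slot, ...], frozenset]]] = None

                def rec(i: int, blocks: list[list[Slot]]) -> None:
                    nonlocal best
                    if best is not None and len(blocks) >= len(best):
                        if i < len(comp) and len(blocks) + 0 >= len(best):
                            return
                    if i == len(comp):
                        cand = [(tuple(b), block_ok(tuple(b))) for b in blocks]
                        if any(c is None for _, c in cand):
                            return
                        if best is None or len(cand) < len(best) or (
                                len(cand) == len(best) and
                                sorted(tuple(sorted(c, key=repr)) for _, c in cand) <
                                sorted(tuple(sorted(c, key=repr)) for _, c in best)):
                            best = cand
                        return
                    r = comp[i]
                    for b in blocks:
                        if all(r2 in adj[r] for r2 in b):
                            b.append(r)
                            if block_ok(tuple(b)) is not None:
                                rec(i + 1, blocks)
                            b.pop()
                    blocks.append([r])
                    rec(i + 1, blocks)
                    blocks.pop()

                rec(0, [])
                assert best is not None
                for block, content in best:
                    gid = len(group_content)
                    group_content.append(content)
                    for r in block:
                        group_of[r] = gid
            else:
                # greedy fallback for very tangled components
                blocks: list[list[Slot]] = []
                for r in comp:
                    placed = False
                    for b in blocks:
                        if all(r2 in adj[r] for r2 in b) and \
                                block_ok(tuple(b + [r])) is not None:
                            b.append(r)
                            placed = True
                            break
                    if not placed:
                        blocks.append([r])
                for b in blocks:
                    gid = len(group_content)
                    group_content.append(block_ok(tuple(b)))
                    for r in b:
                        group_of[r] = gid

        # place left-over items (present in the observation but in neither
        # assigned haplotype).  Placement is part of the parsimony
        # optimization: among feasible placements we minimise catalogue
        # size, then total catalogue content, then a lexicographic key.
        flagged: dict[str, str] = {}
        content = [set(c) for c in group_content]
        group_cap: list[frozenset] = []
        members: dict[int, list[Slot]] = {}
        for r, g in group_of.items():
            members.setdefault(g, []).append(r)
        for g in range(len(content)):
            caps = [cap[r] for r in members[g]]
            group_cap.append(frozenset.intersection(*caps))

        needs: list[tuple[str, Item, tuple[int, ...]]] = []
        for a in self.animals:
            gm = group_of[st.find((a, "m"))]
            gp = group_of[st.find((a, "p"))]
            missing = self.obs[a] - (content[gm] | content[gp])
            for item in sorted(missing, key=repr):
                targets = tuple(sorted({g for g in (gm, gp)
                                        if item in group_cap[g]}))
                if not targets:
                    flagged[a] = "unexplained items in observation"
                    continue
                needs.append((a, item, targets))

        variables = sorted({(g, item) for _, item, targets in needs
                            for g in targets}, key=repr)
        if needs and len(variables) <= 14:
            best_sub = None
            best_key = None
            n_best = 0
            for mask in range(1 << len(variables)):
                chosen = {variables[k] for k in range(len(variables))
                          if mask >> k & 1}
                if not all(any((g, item) in chosen for g in targets)
                           for _, item, targets in needs):
                    continue
                trial = [set(c) for c in content]
                for g, item in chosen:
                    trial[g].add(item)
                if not all(self.partial_valid(frozenset(c)) for c in trial):
                    continue
                cat = {frozenset(c) for c in trial}
                key = (len(cat), sum(len(c) for c in cat),
                       tuple(sorted(tuple(sorted(c, key=repr)) for c in cat)))
                if best_key is None or key < best_key:
                    best_key, best_sub = key, chosen
                    n_best = 1
                elif key[:2] == best_key[:2] and key[2] != best_key[2]:
                    n_best += 1
            if best_sub is not None:
                for g, item in best_sub:
                    content[g].add(item)
                if n_best > 1:
                    for a, item, targets in needs:
                        if len(targets) > 1:
                            flagged.setdefault(a, "ambiguous item placement")
            else:
                for a, *_ in needs:
                    flagged[a] = "unexplained items in observation"
        else:
            # greedy fallback: first feasible side
            for a, item, targets in needs:
                placed = False
                for g in targets:
                    if self.partial_valid(frozenset(content[g] | {item})):
                        content[g].add(item)
                        placed = True
                        break
                if placed:
                    if len(targets) > 1:
                        flagged.setdefault(a, "ambiguous item placement")
                else:
                    flagged[a] = "unexplained items in observation"

        # assemble catalogue (dedupe identical contents)
        uniq: dict[frozenset, int] = {}
        order = sorted(range(len(content)),
                       key=lambda g: tuple(sorted(content[g], key=repr)))
        for g in order:
            uniq.setdefault(frozenset(content[g]), len(uniq))
        catalogue = sorted(uniq, key=uniq.get)

        assignments: dict[str, Optional[tuple[int, int]]] = {}
        sire_used: dict[str, Optional[str]] = {}
        ambiguous: set[str] = set()
        for a in self.animals:
            gm = group_of[st.find((a, "m"))]
            gp = group_of[st.find((a, "p"))]
            hm, hp = frozenset(content[gm]), frozenset(content[gp])
            if hm | hp != self.obs[a]:
                flagged[a] = "unexplained items in observation"
                assignments[a] = None
            else:
                assignments[a] = (uniq[hm], uniq[hp])
        for m in st.meioses:
            child = m.child_slot[0]
            if m.child_slot[1] != "p":
                continue
            if m.detached:
                continue
            if m.chosen_sire is not None:
                sire_used[child] = m.chosen_sire
            else:
                sire_used[child] = None
                if len({s for s, _ in m.options}) > 1:
                    ambiguous.add(child)
        return catalogue, assignments, flagged, sire_used, ambiguous, st.suspects

    # -- public entry --------------------------------------------------------

    def solve(self) -> PhasingSolution:
        st = self._init_state()
        if not self._propagate(st):
            raise MendelianError(self._report(st))
        self._nodes = 0
        complete = self._search(st)
        if not complete:
            raise MendelianError(self._report(st))
        best = None
        best_key = None
        n_optimal = 0
        for s in complete:
            cat, asg, flg, sire, amb, susp = self._finalize(s)
            n_unexplained = sum(v is None for v in asg.values())
            key = (n_unexplained, len(cat),
                   tuple(tuple(sorted(h, key=repr)) for h in cat))
            if best_key is None or key < best_key:
                if best_key is None or key[:2] < best_key[:2]:
                    n_optimal = 1
                best_key = key
                best = (cat, asg, flg, sire, amb, susp)
            elif key[:2] == best_key[:2] and key[2] != best_key[2]:
                n_optimal += 1
        cat, asg, flg, sire, amb, susp = best
        return PhasingSolution(catalogue=cat, assignments=asg, flagged=flg,
                               sire_used=sire, ambiguous_sires=amb,
                               recomb_suspects=susp, n_optimal=max(n_optimal, 1))

    def _report(self, st: _State) -> str:
        bad = []
        for m in st.meioses:
            if m.decided or m.detached:
                continue
            rc = st.find(m.child_slot)
            if not any(self._compatible(st, rc, st.find(slot))
                       for _, slot in m.options):
                child = m.child_slot[0]
                rec = self.pedigree[child]
                bad.append(f"{child} (dam={rec.dam_id}, sires={list(rec.sire_ids)})")
        if not bad:
            # items a child shows that no parent carries at all
            for a in self.animals:
                rec = self.pedigree[a]
                parents = [p for p in (rec.dam_id, *rec.sire_ids)
                           if p in self.obs]
                if not parents:
                    continue
                pool: set = set()
                if rec.dam_id in self.obs:
                    pool |= self.obs[rec.dam_id]
                sire_pool: set = set()
                for sp in rec.sire_ids:
                    if sp in self.obs:
                        sire_pool |= self.obs[sp]
                extra = self.obs[a] - (pool | sire_pool)
                if extra:
                    bad.append(f"{a} (dam={rec.dam_id}, "
                               f"sires={list(rec.sire_ids)}; "
                               f"unexplained items {sorted(extra, key=repr)})")
        if not bad:
            bad = ["<unlocalized>"]
        return ("no consistent haplotype segregation; Mendelian inconsistency in "
                "famil(ies) of: " + ", ".join(sorted(bad)))


# ---------------------------------------------------------------------------
# independent consistency checker (used for under-determination certificates)
# ---------------------------------------------------------------------------

def check_solution(observations: dict[str, frozenset],
                   pedigree: Sequence[PedigreeRecord],
                   catalogue: Sequence[frozenset],
                   assignments: dict[str, Optional[tuple[int, int]]]) -> bool:
    """Verify union and transmission constraints of a phasing, from scratch.

    Pure checker, independent of the solver: every assigned animal's two
    haplotypes must union to its observation, and every assigned
    non-founder must share its maternal haplotype with the dam and its
    paternal haplotype with at least one candidate sire.
    """
    ped = {r.animal_id: r for r in pedigree}
    for a, pair in assignments.items():
        if pair is None:
            return False
        hm, hp = catalogue[pair[0]], catalogue[pair[1]]
        if hm | hp != observations[a]:
            return False
        rec = ped[a]
        if rec.dam_id and rec.dam_id in assignments and assignments[rec.dam_id]:
            dm = {assignments[rec.dam_id][0], assignments[rec.dam_id][1]}
            if pair[0] not in dm:
                return False
        sires = [s for s in rec.sire_ids if s in assignments and assignments[s]]
        if sires:
            ok = any(pair[1] in set(assignments[s]) for s in sires)
            if not ok:
                return False
    return True
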