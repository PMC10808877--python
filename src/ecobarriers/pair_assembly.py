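"""Society pairs, cultural-sharing scores, and transmission covariates.

The unit of analysis is the unordered society pair: each society is paired
with its k geodesic-nearest neighbours (k = 100 in the full design) and
the union is de-duplicated. For every pair and trait, a sharing flag says
whether the two societies carry the same (possibly recoded) trait code;
missing data and trait-specific "absent" codes propagate as missing.
Two pair-level covariates control for confounds of environmental effects:

* *relatedness* — cophenetic (patristic) distance on the language tree,
  absorbing similarity due to common ancestry;
* *neighbourhood transmission* — the mean, over both pair members, of the
  fraction of a member's closest neighbours that carry the partner's
  trait value, absorbing similarity acquired from third parties.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np
import pandas as pd

from .cost_paths import geodesic_km_matrix

__all__ = [
    "MISSING",
    "ABSENT",
    "nearest_pairs",
    "recode",
    "usable_traits",
    "score_sharing",
    "relatedness",
    "cophenetic_table",
    "neighbor_transmission",
]

logger = logging.getLogger(__name__)

MISSING = "missing"
ABSENT = "absent"


def nearest_pairs(societies: pd.DataFrame, k: int = 100) -> pd.DataFrame:
    """Each society paired with its k geodesic-nearest others, de-duplicated.

    Distance ties are broken by id order. Returns columns
    ``id_a``/``id_b`` (lexicographically sorted) and ``geodesic_km``.
    """
    ids = societies["id"].to_numpy()
    order = np.argsort(ids, kind="stable")
    ids = ids[order]
    lats = societies["lat"].to_numpy()[order]
    lons = societies["lon"].to_numpy()[order]
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 societies")
    dist = geodesic_km_matrix(lats, lons)
    kk = min(k, n - 1)
    pairs: set[tuple[int, int]] = set()
    for i in range(n):
        d = dist[i].copy()
        d[i] = np.inf
        nearest = np.argsort(d, kind="stable")[:kk]
        for j in nearest:
            pairs.add((min(i, j), max(i, j)))
    rows = sorted(pairs)
    return pd.DataFrame(
        {
            "id_a": [ids[i] for i, _ in rows],
            "id_b": [ids[j] for _, j in rows],
            "geodesic_km": [dist[i, j] for i, j in rows],
        }
    )


def recode(codes: pd.Series, recoding: dict | None) -> pd.Series:
    """Apply a code->code recoding map; unmapped codes pass through.

    ``MISSING`` and ``ABSENT`` markers are preserved untouched.
    """
    if not recoding:
        return codes
    return codes.map(lambda c: c if c in (MISSING, ABSENT) else recoding.get(c, c))


def _trait_codes(
    trait_table: pd.DataFrame, trait: str, recoding: dict | None = None
) -> pd.Series:
    sub = trait_table[trait_table["trait_id"] == trait]
    if sub.empty:
        raise KeyError(f"unknown trait {trait!r}")
    codes = pd.Series(sub["code"].to_numpy(), index=sub["society_id"].to_numpy())
    codes = codes.where(codes.notna(), MISSING)
    return recode(codes, recoding)


def usable_traits(
    trait_table: pd.DataFrame, recodings: dict[str, dict] | None = None
) -> tuple[list[str], list[str]]:
    """Split traits into usable and rejected by the category-count rule.

    Traits whose recoded (non-missing, non-absent) codes span two or fewer
    discrete categories are rejected: with so few categories the sharing
    flag is uninformative about environmental sorting.
    """
    recodings = recodings or {}
    keep, drop = [], []
    for trait in sorted(trait_table["trait_id"].unique()):
        codes = _trait_codes(trait_table, trait, recodings.get(trait))
        observed = codes[~codes.isin([MISSING, ABSENT])].unique()
        (keep if len(observed) > 2 else drop).append(trait)
    if drop:
        logger.info("usable_traits: rejected %d traits with <=2 categories", len(drop))
    return keep, drop


def score_sharing(
    trait_table: pd.DataFrame,
    trait: str,
    pairs: pd.DataFrame,
    recoding: dict | None = None,
) -> pd.Series:
    """Sharing flag per pair: 1 same recoded code, 0 different, NaN missing.

    A value is missing if either society lacks data or carries the
    trait-specific ``ABSENT`` marker (societies in which the trait of
    interest does not occur are not compared).
    """
    codes = _trait_codes(trait_table, trait, recoding)
    known = set(codes.index)
    for col in ("id_a", "id_b"):
        bad = set(pairs[col]) - known
        if bad:
            raise KeyError(
                f"societies without any row for trait {trait!r}: {sorted(bad)[:5]}"
            )
    a = codes.reindex(pairs["id_a"].to_numpy()).to_numpy()
    b = codes.reindex(pairs["id_b"].to_numpy()).to_numpy()
    out = np.where(a == b, 1.0, 0.0)
    bad_mask = np.isin(a, [MISSING, ABSENT]) | np.isin(b, [MISSING, ABSENT])
    out[bad_mask] = np.nan
    return pd.Series(out, index=pairs.index, name=trait)


def cophenetic_table(tree: dendropy.Tree) -> pd.DataFrame:
    """Patristic (cophenetic) distance matrix between all tree tips."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def relatedness(
    tree_or_table: dendropy.Tree | pd.DataFrame, pairs: pd.DataFrame
) -> pd.Series:
    """Cophenetic distance per pair (sum of branch lengths through the MRCA).

    Pairs whose ids are not tips of the tree get NaN with a logged count
    and are dropped downstream.
    """
    table = (
        tree_or_table
        if isinstance(tree_or_table, pd.DataFrame)
        else cophenetic_table(tree_or_table)
    )
    known = set(table.index)
    vals = np.full(len(pairs), np.nan)
    n_missing = 0
    for r, (a, b) in enumerate(pairs[["id_a", "id_b"]].itertuples(index=False)):
        if a in known and b in known:
            vals[r] = table.at[a, b]
        else:
            n_missing += 1
    if n_missing:
        logger.warning("relatedness: %d pairs missing from the tree", n_missing)
    return pd.Series(vals, index=pairs.index, name="relatedness")


def neighbor_transmission(
    pairs: pd.DataFrame,
    societies: pd.DataFrame,
    trait_table: pd.DataFrame,
    trait: str,
    mode: str = "five_with_data",
    recoding: dict | None = None,
    n_neighbors: int | None = None,
    min_with_data: int = 3,
) -> pd.Series:
    """Potential for trait acquisition from each member's close neighbourhood.

    For pair (A, B) and one direction (A's side): among A's geodesic-
    nearest neighbours — excluding both pair members — count the fraction
    that carry B's trait value. The pair's statistic is the mean of the
    two directions.

    ``mode='five_with_data'`` (main design): the neighbour set is A's 5
    nearest societies *with data* for the trait; no data-bearing
    neighbour at all gives missing.
    ``mode='ten_any'`` (sensitivity design): the neighbour set is the
    fixed 10 nearest societies regardless of data; the denominator is
    those of the 10 with data, and the pair is kept only if at least
    ``min_with_data`` of the 10 have data on both sides.
    """
    if mode not in ("five_with_data", "ten_any"):
        raise ValueError("mode must be 'five_with_data' or 'ten_any'")
    k = n_neighbors or (5 if mode == "five_with_data" else 10)
    codes = _trait_codes(trait_table, trait, recoding)
    ids = societies["id"].to_numpy()
    order = np.argsort(ids, kind="stable")
    ids = ids[order]
    idx = {sid: i for i, sid in enumerate(ids)}
    dist = geodesic_km_matrix(
        societies["lat"].to_numpy()[order], societies["lon"].to_numpy()[order]
    )
    has_data = np.array(
        [codes.get(sid, MISSING) not in (MISSING, ABSENT) for sid in ids]
    )
    code_arr = np.array([codes.get(sid, MISSING) for sid in ids], dtype=object)
    np.fill_diagonal(dist, np.inf)
    order_all = np.argsort(dist, axis=1, kind="stable")  # shared across pairs

    def one_side(focal: str, partner: str) -> float:
        i, j = idx[focal], idx[partner]
        partner_code = code_arr[j]
        if partner_code in (MISSING, ABSENT):
            return np.nan
        pool: list[int] = []
        if mode == "five_with_data":
            for m in order_all[i]:
                # both pair members are excluded from the neighbourhood
                if m == j or not has_data[m]:
                    continue
                pool.append(m)
                if len(pool) == k:
                    break
            if not pool:
                return np.nan
            return float(np.mean(code_arr[pool] == partner_code))
        for m in order_all[i]:
            if m == j:
                continue
            pool.append(m)
            if len(pool) == k:
                break
        with_data = [m for m in pool if has_data[m]]
        if len(with_data) < min_with_data:
            return np.nan
        return float(np.mean(code_arr[with_data] == partner_code))

    vals = np.array(
        [
            np.mean([one_side(a, b), one_side(b, a)])
            for a, b in pairs[["id_a", "id_b"]].itertuples(index=False)
        ]
    )
    return pd.Series(vals, index=pairs.index, name="neighbor_transmission")
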