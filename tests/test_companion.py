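import numpy as np
import pandas as pd
import pytest
from scipy import stats

from domaindiff import (
    ExpressionDataset,
    GeneRecord,
    GenomicDomain,
    artificial_partition,
    assign_genes_to_domains,
    conserved_regions,
    family_network_enrichment,
    filter_cross_boundary,
    flag_immune_domains,
    shared_boundary_ratio,
)
from domaindiff.companion import count_family_edges
from domaindiff.genome import DomainGeneMap


def _doms(spans, chrom="chr1", prefix="d"):
    return [GenomicDomain(chrom, s, e, f"{prefix}{i}") for i, (s, e) in enumerate(spans)]


# --- artificial partitions ---------------------------------------------------

def test_artificial_partition_midpoints():
    art = artificial_partition(_doms([(0, 100), (100, 200)]))
    assert [(a.start, a.end) for a in art] == [(50, 150)]


def test_artificial_partition_counts_and_straddling():
    real = _doms([(0, 100), (100, 220), (220, 400), (400, 480)])
    art = artificial_partition(real)
    assert len(art) == 3
    boundaries = [d.end for d in real[:-1]]
    for a in art:
        inside = [b for b in boundaries if a.start < b <= a.end]
        assert len(inside) == 1  # each artificial domain straddles one boundary


def test_artificial_partition_single_domain_chromosome_skipped():
    assert artificial_partition(_doms([(0, 100)])) == []


def test_filter_cross_boundary_excludes_single_source():
    real = _doms([(0, 100), (100, 200), (200, 300)])
    # genes: two left of boundary at 100 (in real d0), one right (real d1),
    # and an artificial domain [150,250) whose genes all come from real d1
    genes = [
        GeneRecord("gA", "chr1", "+", 60, 70),
        GeneRecord("gB", "chr1", "+", 80, 90),
        GeneRecord("gC", "chr1", "+", 110, 130),
        GeneRecord("gD", "chr1", "+", 160, 170),
        GeneRecord("gE", "chr1", "+", 180, 190),
    ]
    art = artificial_partition(real)  # [50,150), [150,250)
    art_map = assign_genes_to_domains(genes, art)
    real_map = assign_genes_to_domains(genes, real)
    kept = filter_cross_boundary(art_map, real_map)
    # [50,150) holds gA,gB (real d0) + gC (real d1) -> mixed, kept
    # [150,250) holds gD,gE (both real d1) -> excluded
    assert kept.domain_ids() == ["Achr1.0"]


# --- shared boundaries -------------------------------------------------------

def test_shared_boundary_identical_partitions():
    a = _doms([(0, 40_000 * 10), (40_000 * 10, 40_000 * 25)])
    assert shared_boundary_ratio(a, a) == 1.0


@pytest.mark.parametrize("shift_bins,expected", [(2, 1.0), (3, 0.0)])
def test_shared_boundary_tolerance_radius(shift_bins, expected):
    bs = 40_000
    a = _doms([(0, 10 * bs), (10 * bs, 25 * bs)])
    shift = shift_bins * bs
    b = _doms([(shift, 10 * bs + shift), (10 * bs + shift, 25 * bs + shift)], prefix="b")
    assert shared_boundary_ratio(a, b, bin_size=bs, tolerance_bins=2) == expected


def test_shared_boundary_empty_partition_errors():
    with pytest.raises(ValueError):
        shared_boundary_ratio([], _doms([(0, 10)]))


# --- immune domains ----------------------------------------------------------

def _purity_setup(seed=0, n_domains=40, coupled=()):
    rng = np.random.default_rng(seed)
    n_genes = n_domains * 3
    samples = [f"s{i}" for i in range(20)]
    purity = {s: float(v) for s, v in zip(samples, rng.beta(5, 2, 20))}
    pur = np.array([purity[s] for s in samples])
    x = rng.lognormal(3, 1, size=(n_genes, 20))
    doms, assign = [], {}
    for d in range(n_domains):
        rows = [3 * d, 3 * d + 1, 3 * d + 2]
        if d in coupled:
            for r in rows:
                x[r] = np.exp(-3 * (pur - pur.mean()) + rng.normal(0, 0.1, 20) + 3)
        doms.append(GenomicDomain("chr1", 1000 * d, 1000 * (d + 1), f"d{d}"))
        assign[f"d{d}"] = [f"g{r}" for r in rows]
    values = pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)], columns=samples)
    cond = {s: ("A" if i < 10 else "B") for i, s in enumerate(samples)}
    ds = ExpressionDataset(values, cond)
    return ds, DomainGeneMap(assign, doms), purity


def test_immune_flags_quantile_of_reference():
    ds, gmap, purity = _purity_setup()
    ref = set(gmap.domain_ids())
    out = flag_immune_domains(ds, gmap, purity, reference=ref)
    # purity independent of expression and correlations untied: the threshold
    # is the 0.05-quantile of 40 reference values, so exactly 2 fall at/below
    assert out["immune"].sum() == int(np.ceil(0.05 * len(ref)))


def test_immune_planted_confounder_flagged_first():
    ds, gmap, purity = _purity_setup(seed=1, coupled=(7,))
    ref = set(gmap.domain_ids()) - {"d7"}
    out = flag_immune_domains(ds, gmap, purity, reference=ref)
    assert out.loc["d7", "immune"]
    assert out["purity_cor"].idxmin() == "d7"


def test_immune_constant_purity_errors():
    ds, gmap, _ = _purity_setup()
    with pytest.raises(ValueError, match="constant purity"):
        flag_immune_domains(ds, gmap, {s: 0.5 for s in ds.samples},
                            reference=set(gmap.domain_ids()))


# --- gene family networks ----------------------------------------------------

def _family_fixture():
    # 4 domains x 4 genes on one chromosome; family F occupies all of d1
    genes, doms, assign = [], [], {}
    fam = {}
    g = 0
    for d in range(4):
        doms.append(GenomicDomain("chr1", 10_000 * d, 10_000 * (d + 1), f"d{d}"))
        ids = []
        for j in range(4):
            gid = f"g{g}"
            genes.append(GeneRecord(gid, "chr1", "+", 10_000 * d + 1000 * j + 10,
                                    10_000 * d + 1000 * j + 500))
            fam[gid] = "other"
            ids.append(gid)
            g += 1
        assign[f"d{d}"] = ids
    for gid in assign["d1"]:
        fam[gid] = "F"
    return DomainGeneMap(assign, doms), genes, fam


def test_family_clustered_complete_graph():
    gmap, genes, fam = _family_fixture()
    res = family_network_enrichment(gmap, genes, fam, n_perm=20, seed=0)
    assert res["F"].observed_edges == 4 * 3 // 2  # complete graph on 4 genes


def test_family_dispersed_zero_edges():
    gmap, genes, fam = _family_fixture()
    # move family members to one per domain
    fam = {g: "other" for g in fam}
    for d in range(4):
        fam[gmap[f"d{d}"][0]] = "F"
    res = family_network_enrichment(gmap, genes, fam, n_perm=20, seed=0)
    assert res["F"].observed_edges == 0


def test_family_observed_matches_bruteforce_pairs():
    gmap, genes, fam = _family_fixture()
    members = {g for g, f in fam.items() if f == "F"}
    qualifying = [d for d in gmap
                  if sum(fam[g] == "F" for g in gmap[d]) / len(gmap[d]) >= 0.5]
    expected = sum(
        1 for d in qualifying
        for i, a in enumerate([g for g in gmap[d] if g in members])
        for b in [g for g in gmap[d] if g in members][i + 1:]
    )
    res = family_network_enrichment(gmap, genes, fam, n_perm=5, seed=0)
    assert res["F"].observed_edges == expected == len(count_family_edges(gmap, members, qualifying))


def test_family_enrichment_direction():
    """A clustered family has far more observed than expected edges."""
    gmap, genes, fam = _family_fixture()
    res = family_network_enrichment(gmap, genes, fam, n_perm=50, seed=3)
    assert res["F"].observed_edges > res["F"].expected_edges


def test_family_first_level_resolution():
    from domaindiff.companion import resolve_families
    assert resolve_families({"g": "Collagens|Collagen proteoglycans"}) == {"g": "Collagens"}


# --- conserved regions -------------------------------------------------------

def _gene_sets(domains_by_ds, genes_by_domain):
    return {name: {d.domain_id: genes_by_domain.get(d.domain_id, [])
                   for d in doms} for name, doms in domains_by_ds.items()}


def test_conserved_identical_domain_two_datasets():
    d1 = GenomicDomain("chr1", 0, 1000, "x")
    d2 = GenomicDomain("chr1", 0, 1000, "y")
    sets = {"ds1": [d1], "ds2": [d2]}
    gs = _gene_sets(sets, {"x": ["a", "b", "c"], "y": ["a", "b", "c"]})
    regions = conserved_regions(sets, gs)
    assert len(regions) == 1
    assert regions[0].support == 2
    assert regions[0].genes == {"a", "b", "c"}


def test_conserved_half_overlap_rejected():
    d1 = GenomicDomain("chr1", 0, 1000, "x")
    d2 = GenomicDomain("chr1", 500, 1500, "y")
    sets = {"ds1": [d1], "ds2": [d2]}
    gs = _gene_sets(sets, {"x": ["a", "b", "c"], "y": ["a", "b", "c"]})
    assert conserved_regions(sets, gs) == []


def test_conserved_five_dataset_panel_matches_enumeration():
    shared = [GenomicDomain("chr2", 10_000, 20_000, f"s{i}") for i in range(5)]
    extra = GenomicDomain("chr2", 50_000, 60_000, "lone")
    sets = {f"ds{i}": [shared[i]] for i in range(5)}
    sets["ds0"] = [shared[0], extra]
    genes = {d.domain_id: ["p", "q", "r"] for d in shared}
    genes["lone"] = ["u", "v", "w"]
    regions = conserved_regions(sets, _gene_sets(sets, genes))
    assert len(regions) == 1
    assert regions[0].support == 5
    assert (regions[0].start, regions[0].end) == (10_000, 20_000)


def test_conserved_gene_share_merging():
    a1 = GenomicDomain("chr1", 0, 1000, "a1")
    a2 = GenomicDomain("chr1", 0, 1000, "a2")
    b1 = GenomicDomain("chr1", 2000, 3000, "b1")
    b2 = GenomicDomain("chr1", 2050, 3050, "b2")
    sets = {"ds1": [a1, b1], "ds2": [a2, b2]}
    genes = {"a1": ["x", "y", "z"], "a2": ["x", "y", "z"],
             "b1": ["x", "y", "z", "w"], "b2": ["x", "y", "z", "w"]}
    regions = conserved_regions(sets, _gene_sets(sets, genes))
    # the two regions share all 3 intersect genes of the smaller -> merged
    assert len(regions) == 1
    assert regions[0].genes >= {"x", "y", "z"}
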