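import numpy as np
import pandas as pd
import pytest

from rohdep.io_formats import GenotypeMatrix, make_pedigree, make_snp_map


@pytest.fixture
def toy_map():
    return make_snp_map([f"s{i}" for i in range(5)],
                        [1, 1, 1, 2, 2],
                        [100, 200, 300, 100, 250],
                        ["A"] * 5, ["B"] * 5)


@pytest.fixture
def fullsib_pedigree():
    """Offspring of full sibs whose parents are unrelated founders."""
    return make_pedigree([
        ("gs", None, None), ("gd", None, None),
        ("s", "gs", "gd"), ("d", "gs", "gd"),
        ("x", "s", "d"),
    ])


@pytest.fixture
def halfsib_pedigree():
    return make_pedigree([
        ("gs", None, None), ("gd1", None, None), ("gd2", None, None),
        ("s", "gs", "gd1"), ("d", "gs", "gd2"),
        ("x", "s", "d"),
    ])


def random_pedigree(rng, n_founders=5, n_extra=15):
    """Tangled random pedigree for oracle comparisons."""
    records = [(f"f{i}", None, None) for i in range(n_founders)]
    ids = [r[0] for r in records]
    for k in range(n_extra):
        s, d = rng.choice(len(ids), size=2, replace=True)
        if s == d:
            d = (d + 1) % len(ids)
        records.append((f"a{k}", ids[s], ids[d]))
        ids.append(f"a{k}")
    return make_pedigree(records)


def kinship_oracle(ped):
    """Independent recursive-coancestry implementation of pedigree
    inbreeding: F_x = f(sire_x, dam_x) with the classical recursion."""
    par = {r.animal: (r.sire, r.dam) for r in ped.itertuples(index=False)}
    order = {a: i for i, a in enumerate(ped["animal"])}
    memo = {}

    def f(a, b):
        if a is None or b is None:
            return 0.0
        if order[a] > order[b]:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        sb, db = par[b]
        if a == b:
            val = 0.5 * (1.0 + f(sb, db))
        else:
            val = 0.5 * (f(a, sb) + f(a, db))
        memo[key] = val
        return val

    return {a: f(*par[a]) for a in ped["animal"]}


def random_genotypes(rng, n_animals, n_snps, n_chrom=2, spacing=100_000,
                     hom_bias=0.5):
    """Random genotype matrix; hom_bias raises homozygosity so ROH appear."""
    per = n_snps // n_chrom
    chrom = np.repeat(np.arange(1, n_chrom + 1), per)
    pos = np.tile(np.arange(1, per + 1) * spacing, n_chrom)
    snp_map = make_snp_map([f"s{i}" for i in range(per * n_chrom)], chrom,
                           pos, ["A"] * (per * n_chrom),
                           ["B"] * (per * n_chrom))
    codes = rng.choice([0, 1, 2], size=(n_animals, per * n_chrom),
                       p=[hom_bias / 2, 1 - hom_bias, hom_bias / 2])
    return GenotypeMatrix([f"an{i}" for i in range(n_animals)], snp_map,
                          codes.astype(np.int8))


def roh_bruteforce(geno, params):
    """Literal re-implementation of the five-rule sliding-window ROH scan,
    kept deliberately loop-based and independent of the production caller."""
    L = params.window_snps
    segs = []
    for ai, animal in enumerate(geno.samples):
        for chrom in sorted(geno.snp_map["chrom"].unique()):
            sel = geno.snp_map["chrom"] == chrom
            pos = geno.snp_map.loc[sel, "pos_bp"].to_numpy()
            g = geno.codes[ai, sel.to_numpy()]
            n = len(g)
            if n < L:
                continue
            win_ok = []
            for w in range(n - L + 1):
                window = g[w:w + L]
                het = int((window == 1).sum())
                mis = int((window == -1).sum())
                win_ok.append(het <= params.max_het_per_window
                              and mis <= params.max_missing_per_window)
            elig = []
            for k in range(n):
                covering = [win_ok[w] for w in range(max(0, k - L + 1),
                                                    min(n - L, k) + 1)]
                elig.append(sum(covering) / len(covering)
                            >= params.window_hit_proportion)
            # maximal eligible runs, split at large gaps
            runs, cur = [], []
            for k in range(n):
                if not elig[k]:
                    if cur:
                        runs.append(cur)
                        cur = []
                    continue
                if cur and (pos[k] - pos[cur[-1]]) / 1000.0 > params.max_gap_kb:
                    runs.append(cur)
                    cur = []
                cur.append(k)
            if cur:
                runs.append(cur)
            for run in runs:
                length_kb = (pos[run[-1]] - pos[run[0]] + 1) / 1000.0
                if (length_kb >= params.min_length_kb
                        and len(run) >= params.min_snps
                        and length_kb / len(run)
                        <= params.min_density_kb_per_snp):
                    cls = ("ROH2_8" if length_kb < params.class_boundary_kb
                           else "ROH8")
                    segs.append((animal, int(chrom), int(pos[run[0]]),
                                 int(pos[run[-1]]), len(run),
                                 float(length_kb), cls))
    return pd.DataFrame(segs, columns=["animal_id", "chrom", "start_bp",
                                       "end_bp", "n_snps", "length_kb",
                                       "length_class"])
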