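"""Detect co-searching acquaintances and measure their structure.

A co-search pair is a contact edge whose endpoints both entered the
cohort. The generator plants 6x more such pairs than label-permutation
chance, with disease concordance, severity-specific onset lags and
shorter acquaintance searches for indolent diseases.
"""

from seekpaths import (
    SyntheticConfig,
    build_profiles,
    enrichment_vs_chance,
    find_pairs,
    lag_duration_contrasts,
    overlap_stats,
    simulate_log,
)
from seekpaths.cohort import partition_severity

events, contacts, lexicon = simulate_log(SyntheticConfig(n_users=20_000, seed=3))
profiles, _ = build_profiles(events, partition_severity(lexicon))
edges = contacts.to_numpy()
pairs = find_pairs(profiles, edges)
print(f"{len(pairs)} co-search pairs among {len(profiles)} included users")

enr = enrichment_vs_chance(len(pairs), profiles, edges, n_permutations=500, seed=4)
print(f"fold enrichment over chance: {enr['fold_enrichment']:.1f} "
      f"(expected {enr['expected_by_chance']:.0f} pairs, p = {enr['p_value']:.3f})")

ov = overlap_stats(pairs, profiles, seed=5)
print(f"disease overlap within pairs: {ov['observed_overlap']:.2f} "
      f"vs {ov['random_match_baseline']:.2f} for random matching")

contrasts = lag_duration_contrasts(pairs)
for sev, s in contrasts["strata"].items():
    print(f"{sev}: {s['n_pairs']} pairs, onset lag {s['lag_mean']:.1f} d, "
          f"proband {s['first_duration_mean']:.1f} d vs "
          f"acquaintance {s['second_duration_mean']:.1f} d "
          f"(sign test p = {s['duration_sign_test']['p_value']:.2g})")
# Acquaintances start later for indolent diseases and search much more
# briefly than the proband; for aggressive diseases the two are similar.
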