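"""Reproduce the published reference-pair recommendations.

Feeds the printed per-gene delta-CT stability statistics for each of the 15
condition strata (4 stresses + all-stress, by roots / shoots / combined) to
the recommendation stage and compares against the published pairs.
"""

from refstab import DeltaCtResult, recommend_pairs
from refstab import published as pub

columns = {("all", k): v for k, v in pub.DELTACT_ALL_STRESS.items()}
for stress, strata in pub.DELTACT_BY_STRESS.items():
    for stratum, vals in strata.items():
        columns[(stress, stratum)] = vals

print(f"{'condition':<22} {'recommended':<14} {'statistics (cycles)':<20} published")
matches = 0
for key in sorted(columns):
    rec = recommend_pairs(DeltaCtResult.from_mean_sd(columns[key]), condition=key)
    expected = pub.RECOMMENDED_PAIRS[key]
    ok = rec.pair == expected
    matches += ok
    print(f"{key[0] + '/' + key[1]:<22} {rec.pair[0] + '/' + rec.pair[1]:<14} "
          f"{rec.statistics[0]:.4f}, {rec.statistics[1]:.4f}      "
          f"{expected[0]}/{expected[1]} {'OK' if ok else 'MISMATCH'}")
print(f"\n{matches}/15 published pairs reproduced by the top-2-by-delta-CT rule.")
print("The statistic is the gene's mean pairwise SD of delta-CT: lower means "
      "its expression moves less against the other candidates.")
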