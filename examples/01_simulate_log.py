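"""Generate a synthetic cancer query log and inspect its shape.

The generator emulates the statistical structure of a three-month web
search log: heavy-tailed activity per user, a contact graph with
power-law degrees, severity-dependent category journeys and planted
co-searching acquaintance pairs.
"""

from seekpaths import SyntheticConfig, simulate_log

config = SyntheticConfig(n_users=5_000, seed=42)
events, contacts, lexicon = simulate_log(config)

print(f"{len(events)} page-visit events from {events['user_id'].nunique()} users")
print(f"{len(contacts)} contact edges over a universe of "
      f"{config.network_scale * config.n_users} people")
print(f"lexicon: {len(lexicon)} cancers, e.g. {lexicon['cancer'].iloc[0]!r}")
print("\nfirst rows of the log:")
print(events.head(5).to_string(index=False))

# Each row is one page visit: the day within the 92-day window, the
# templated query text, the cancer the query names, and the visited
# page's thematic category.
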