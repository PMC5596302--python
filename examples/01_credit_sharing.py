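"""How one response's engagement unit is shared along a subthread.

Builds the illustrative 8-post thread (root by A; B and C reply to A; a
deeper A-B-D-B branch where B self-engages) and prints the forum's total
engagement value and each contributor's capacity.
"""

from ohf_engage import EngagementParams, compute_ledger, credit_shares
from ohf_engage.synthetic_data import fixture_known_answer

ds, expected = fixture_known_answer()
params = EngagementParams(alpha=0.8)

ledger = compute_ledger(ds, params)
print(f"total engagement value: {ledger.total_value:.0f} "
      f"({ds.n_posts} posts, {ds.n_posts - len(ds.threads)} of them responses)")
for user in sorted(ledger.capacity, key=ledger.capacity.get, reverse=True):
    print(f"  capacity[{user}] = {ledger.capacity[user]:.4f}")

# the A-B-D-B subthread: a new response to its leaf splits one unit with
# geometric discounting (leaf 1, then 0.8, 0.64, 0.512 up-thread)
sub = ds.threads[0].posts[:2] + ds.threads[0].posts[3:5]  # A, B, D, B path
shares = credit_shares(sub, params)
print("shares of one unit for a response to the A-B-D-B subthread:")
for user, share in sorted(shares.items(), key=lambda kv: -kv[1]):
    print(f"  {user}: {share:.4f}")
print("B's share exceeds 1/3: self-engagement rewards repeat contributors;")
print("the capacities above sum to the total value (conservation).")
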