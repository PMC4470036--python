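"""Centroid-based molecular subtyping of expression profiles.

Samples are drawn around synthetic subtype centroids, classified by Pearson
correlation to each centroid (assignment = highest correlation; confidence
= margin over the runner-up), and ordered by hierarchical clustering of the
correlation vectors.
"""
import allelic_cna as ac

centroids = ac.make_demo_centroids(n_genes=200, seed=0)
classes = list(centroids.columns)
assignment = {f"line{i:02d}": classes[i % len(classes)] for i in range(12)}
spread = centroids.to_numpy().std()
expr = ac.simulate_expression(centroids, assignment, sd=0.25 * spread, seed=1)

result = ac.classify_by_centroids(expr, centroids)
print(result.round(3).to_string(index=False))

n_correct = sum(result.set_index("sample").at[s, "assigned"] == c
                for s, c in assignment.items())
print(f"\nrecovered {n_correct}/{len(assignment)} planted subtypes")

order = ac.correlation_cluster(result.set_index("sample")[classes])
print("dendrogram leaf order:", ", ".join(order))
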