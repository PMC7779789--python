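"""Score a handful of posts against toy lexicons, showing the negation rule.

Every lexicon word found in a post contributes its weight to its
category; a word directly preceded by a negator ("not", "不") counts
with reversed sign.
"""

import datetime as dt

from emoprosocial import Lexicon, LexiconEntry, Post, filter_posts, score_post

emotion = Lexicon(
    entries=[
        LexiconEntry("开心", "happiness", 5.0),
        LexiconEntry("愤怒", "anger", 7.0),
        LexiconEntry("害怕", "fear", 6.0),
    ],
    kind="emotion",
)
prosocial = Lexicon(
    entries=[
        LexiconEntry("捐赠", "prosocial", 8.2),
        LexiconEntry("帮助", "prosocial", 6.5),
        LexiconEntry("志愿", "prosocial", 7.8),
    ],
    kind="prosocial",
)
negators = ["不", "没有"]

posts = [
    Post("p1", "u1", dt.date(2020, 1, 25), "今天帮助邻居买菜，很开心"),
    Post("p2", "u2", dt.date(2020, 1, 25), "我不捐赠"),
    Post("p3", "u3", dt.date(2020, 1, 25), "官方通告", is_official=True),
    Post("p4", "u4", dt.date(2020, 1, 25), "转发内容", is_repost=True,
         repost_comment="志愿者加油，不害怕"),
]

kept, drops = filter_posts(posts)
print(f"kept {len(kept)} posts; drops by reason: {drops}\n")

for p in kept:
    scores = score_post(p, emotion, prosocial, negators)
    nonzero = {c: round(v, 2) for c, v in scores.scores.items() if v != 0.0}
    print(f"{p.post_id}  '{p.text}'")
    print(f"     -> {nonzero}")

print("\np2 scores prosocial -8.2: '捐赠' (weight 8.2) follows the negator '不'.")
print("p4 keeps only the repost comment; '不害怕' reverses fear to -6.0.")
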