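"""Bundled word lists for the synthetic summary generator.

Hand-written, neutral vocabulary themed on the three clinical aspects of a
timeline summary (mental-state words, relationship words, change words).
Contains no real user content and no quoted text from any dataset.

``TEMPLATES`` holds 20 sentence templates per aspect; a system profile draws
uniformly from the first ``template_pool_size`` of them, so a small pool
forces template reuse (low surface diversity) and the full pool maximizes
variety. ``THESAURUS`` maps template words to single-token synonyms for
synonym substitution. ``PERSONAL_TOKENS`` supplies distinct timeline-specific
content words (hobby/topic nouns) whose insertion makes summaries
idiosyncratic per timeline.
"""

from __future__ import annotations

ASPECT_NAMES = ("mental_state", "patterns", "changes_over_time")

TEMPLATES: dict[str, tuple[str, ...]] = {
    "mental_state": (
        "the writer reports feeling low and tired on most days",
        "posts often describe an anxious mood with strong worry",
        "the writer talks about stress and poor sleep in this period",
        "entries show a mild but persistent sense of feeling overwhelmed",
        "the writer reports feeling lonely and low in recent posts",
        "mood appears stable with occasional anxious spells",
        "the writer often mentions feeling angry and tired after work",
        "posts suggest a calm baseline with sudden dips in mood",
        "the writer describes strong stress around school and sleep",
        "a hopeful tone appears alongside reports of feeling low",
        "the writer expresses mild worry about work and family",
        "recent posts show strong feelings of being overwhelmed",
        "the writer describes a tired and anxious state most mornings",
        "entries often mention low mood paired with poor sleep",
        "the writer notes a calm mood when stress at work is mild",
        "posts describe angry outbursts followed by feeling lonely",
        "the writer reports hopeful stretches between anxious periods",
        "a strong sense of stress dominates the recent entries",
        "the writer mentions feeling stable yet tired through the period",
        "mood in the posts moves between calm and overwhelmed states",
    ),
    "patterns": (
        "the writer seeks support from friends when stress is strong",
        "conflict with family often precedes a low mood",
        "the writer avoids closeness after criticism from a partner",
        "posts show a pattern of seeking support then pulling to distance",
        "tension at work often spills into conflict with friends",
        "the writer talks to family for support during anxious spells",
        "criticism from peers leads the writer to avoid social posts",
        "the writer shows warmth toward friends despite frequent conflict",
        "distance from the partner grows whenever stress increases",
        "the writer often seeks closeness and then reports disappointment",
        "support from family appears to steady the writer's mood",
        "the writer avoids conflict by withdrawing from friends",
        "posts reveal a cycle of criticism followed by isolation",
        "the writer mentions strong support from one close friend",
        "interpersonal conflict at school recurs across the posts",
        "the writer shows a pattern of blaming themselves after conflict",
        "closeness with family increases when work stress is mild",
        "the writer describes friction with a partner over small matters",
        "peer support often follows the writer's requests for help",
        "the writer alternates between seeking company and distance",
    ),
    "changes_over_time": (
        "mood improves gradually toward the end of the timeline",
        "a sudden drop in mood follows a period of stable sleep",
        "stress worsens across the period before a slow recovery",
        "the writer's tone begins low and brightens in later posts",
        "sleep improves while mood stays stable through the period",
        "a gradual decline appears after an early hopeful stretch",
        "the posts end on a calmer note than they begin",
        "sudden changes in mood become less frequent over time",
        "the writer reports steady improvement after seeking support",
        "a stable early period gives way to rising stress",
        "later entries show fewer angry posts than earlier ones",
        "the period ends with a sudden return of anxious feelings",
        "gradual gains in sleep precede the improvement in mood",
        "the timeline shows a slow shift from conflict to calm",
        "worry about work fades gradually in the later posts",
        "an abrupt change follows the conflict described midway",
        "the writer's loneliness lessens toward the final entries",
        "early optimism worsens into a tired and low stretch",
        "the final posts suggest a stable and hopeful outlook",
        "recovery begins after the lowest point of the period",
    ),
}

THESAURUS: dict[str, tuple[str, ...]] = {
    "low": ("down", "sad", "gloomy", "blue"),
    "anxious": ("worried", "nervous", "uneasy", "tense"),
    "tired": ("weary", "drained", "exhausted", "fatigued"),
    "hopeful": ("optimistic", "encouraged", "positive"),
    "overwhelmed": ("swamped", "overloaded", "burdened"),
    "angry": ("irritable", "frustrated", "resentful"),
    "calm": ("settled", "steady", "composed"),
    "lonely": ("isolated", "alone", "disconnected"),
    "reports": ("describes", "mentions", "expresses", "notes"),
    "describes": ("reports", "depicts", "recounts"),
    "mentions": ("notes", "cites", "raises"),
    "feeling": ("being", "seeming"),
    "often": ("frequently", "regularly", "repeatedly"),
    "occasional": ("intermittent", "sporadic", "periodic"),
    "strong": ("intense", "marked", "pronounced"),
    "mild": ("slight", "faint", "modest"),
    "friends": ("companions", "peers", "mates"),
    "family": ("relatives", "household", "kin"),
    "partner": ("spouse", "companion"),
    "support": ("help", "backing", "assistance"),
    "conflict": ("tension", "friction", "discord"),
    "criticism": ("judgment", "disapproval", "blame"),
    "closeness": ("intimacy", "connection", "warmth"),
    "distance": ("withdrawal", "detachment", "avoidance"),
    "improves": ("recovers", "rebounds", "brightens"),
    "worsens": ("declines", "deteriorates", "darkens"),
    "stable": ("steady", "constant", "unchanged"),
    "gradual": ("slow", "measured", "incremental"),
    "gradually": ("slowly", "steadily", "incrementally"),
    "sudden": ("abrupt", "sharp", "rapid"),
    "sleep": ("rest", "slumber"),
    "mood": ("spirits", "affect", "morale"),
    "stress": ("pressure", "strain", "load"),
    "work": ("job", "employment"),
    "school": ("college", "classes", "studies"),
    "talks": ("speaks", "writes", "posts"),
    "seeks": ("requests", "asks", "pursues"),
    "seeking": ("requesting", "pursuing"),
    "avoids": ("shuns", "evades", "dodges"),
    "shows": ("displays", "exhibits", "reveals"),
    "begins": ("starts", "commences"),
    "ends": ("stops", "ceases", "concludes"),
    "period": ("phase", "stretch", "interval"),
    "recent": ("latest", "newest", "current"),
    "writer": ("author", "poster", "user"),
    "posts": ("entries", "messages", "updates"),
    "improvement": ("recovery", "progress", "gains"),
    "worry": ("concern", "unease", "apprehension"),
}

PERSONAL_TOKENS: tuple[str, ...] = (
    "gardening", "painting", "chess", "cycling", "baking", "astronomy",
    "pottery", "guitar", "swimming", "hiking", "photography", "knitting",
    "fishing", "origami", "calligraphy", "birdwatching", "skating",
    "drumming", "archery", "sailing", "surfing", "climbing", "camping",
    "jogging", "yoga", "sculpting", "sketching", "quilting", "woodwork",
    "brewing", "beekeeping", "stargazing", "puzzles", "poetry", "violin",
    "piano", "trumpet", "ceramics", "robotics", "coding", "gaming",
    "cooking", "dancing", "theater", "choir", "karate", "judo", "rowing",
    "bowling", "darts", "billiards", "skiing", "snowboarding", "kayaking",
    "canoeing", "orienteering", "geocaching", "foraging", "mushrooming",
    "embroidery", "crochet", "weaving", "leatherwork", "metalwork",
    "glassblowing", "bonsai", "aquariums", "terrariums", "falconry",
    "fencing", "badminton", "squash", "handball",
)

#: Largest template pool any profile may request.
MAX_TEMPLATE_POOL = min(len(v) for v in TEMPLATES.values())
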