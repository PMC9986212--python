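item_id,label,syndrome,WithdrawnDepressed,ThoughtProblems,SocialProblems,ASDProfile,WTP,Ooi,So,DataDriven,ClinicianExpert,Affective,Anxiety,ADH,ODD,Conduct
1,Acts too young for his/her age,AttentionProblems,0,0,0,0,0,1,1,1,1,0,0,0,0,0
2,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
3,,none,0,0,0,0,0,0,0,0,0,0,0,0,1,0
4,,none,0,0,0,0,0,0,0,0,0,0,0,1,0,0
5,There is little that he/she enjoys,WithdrawnDepressed,1,0,0,1,1,0,0,1,1,1,0,0,0,0
6,Bowel movements outside toilet,OtherProblems,0,0,0,0,0,0,0,0,1,0,0,0,0,0
7,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
8,,none,0,0,0,0,0,0,0,0,0,0,0,1,0,0
9,Cannot get his/her mind off certain thoughts; obsessions,ThoughtProblems,0,1,0,1,1,0,1,1,1,0,0,0,0,0
10,,none,0,0,0,0,0,0,0,0,0,0,0,1,0,0
11,Clings to adults or too dependent,SocialProblems,0,0,1,1,0,0,0,1,0,0,1,0,0,0
12,Complains of loneliness,SocialProblems,0,0,1,1,0,0,0,0,0,0,0,0,0,0
13,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
14,,none,0,0,0,0,0,0,0,0,0,1,0,0,0,0
15,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
16,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
17,Daydreams or gets lost in his/her thoughts,AttentionProblems,0,0,0,0,0,0,1,1,1,0,0,0,0,0
18,Deliberately harms self or attempts suicide,ThoughtProblems,0,1,0,1,1,0,0,0,0,1,0,0,0,0
19,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
20,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
21,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
22,,none,0,0,0,0,0,0,0,0,0,0,0,0,1,0
23,,none,0,0,0,0,0,0,0,0,0,0,0,0,1,0
24,Doesn't eat well,OtherProblems,0,0,0,0,0,0,0,0,1,1,0,0,0,0
25,Doesn't get along with other kids,SocialProblems,0,0,1,1,0,1,0,1,1,0,0,0,0,0
26,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
27,Easily jealous,SocialProblems,0,0,1,1,0,0,0,0,0,0,0,0,0,0
28,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
29,"Fears certain animals, situations, or places other than school",AnxiousDepressed,0,0,0,0,0,1,0,0,1,0,1,0,0,0
30,,none,0,0,0,0,0,0,0,0,0,0,1,0,0,0
31,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
32,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
33,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
34,Feels others are out to get him/her,SocialProblems,0,0,1,1,0,0,0,0,0,0,0,0,0,0
35,,none,0,0,0,0,0,0,0,0,0,1,0,0,0,0
36,Gets hurt a lot,SocialProblems,0,0,1,1,0,0,0,0,0,0,0,0,0,0
37,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
38,Gets teased a lot,SocialProblems,0,0,1,1,0,0,0,0,1,0,0,0,0,0
39,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
40,Hears sounds or voices that are not there,ThoughtProblems,0,1,0,1,1,0,0,0,0,0,0,0,0,0
41,,none,0,0,0,0,0,0,0,0,0,0,0,1,0,0
42,Would rather be alone than with others,WithdrawnDepressed,1,0,0,1,1,1,1,1,1,0,0,0,0,0
43,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
44,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
45,"Nervous, high-strung, or tense",AnxiousDepressed,0,0,0,0,0,1,0,0,0,0,1,0,0,0
46,Nervous movements or twitching,ThoughtProblems,0,1,0,1,1,0,0,0,0,0,0,0,0,0
47,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
48,Not liked by other kids,SocialProblems,0,0,1,1,0,0,0,0,1,0,0,0,0,0
49,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
50,,none,0,0,0,0,0,0,0,0,0,0,1,0,0,0
51,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
52,,none,0,0,0,0,0,0,0,0,0,1,0,0,0,0
53,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
54,,none,0,0,0,0,0,0,0,0,0,1,0,0,0,0
55,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
56,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
57,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
58,"Picks nose, skin, or other parts of body",ThoughtProblems,0,1,0,1,1,0,0,0,0,0,0,0,0,0
59,Plays with own sex parts in public,ThoughtProblems,0,1,0,1,1,0,0,0,0,0,0,0,0,0
60,Plays with own sex parts too much,ThoughtProblems,0,1,0,1,1,0,0,0,0,0,0,0,0,0
61,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
62,Poorly coordinated or clumsy,SocialProblems,0,0,1,1,0,0,1,1,0,0,0,0,0,0
63,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
64,Prefers being with younger kids,SocialProblems,0,0,1,1,0,0,0,1,1,0,0,0,0,0
65,Refuses to talk,WithdrawnDepressed,1,0,0,1,1,0,0,0,0,0,0,0,0,0
66,Repeats certain acts over and over; compulsions,ThoughtProblems,0,1,0,1,1,1,1,1,1,0,0,0,0,0
67,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
68,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
69,"Secretive, keeps things to self",WithdrawnDepressed,1,0,0,1,1,0,0,0,1,0,0,0,0,0
70,Sees things that are not there,ThoughtProblems,0,1,0,1,1,0,0,0,0,0,0,0,0,0
71,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
72,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
73,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
74,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
75,Too shy or timid,WithdrawnDepressed,1,0,0,1,1,0,0,1,1,0,0,0,0,0
76,Sleeps less than most kids,ThoughtProblems,0,1,0,1,1,0,0,0,0,1,0,0,0,0
77,,none,0,0,0,0,0,0,0,0,0,1,0,0,0,0
78,,none,0,0,0,0,0,0,0,0,0,0,0,1,0,0
79,Speech problem,SocialProblems,0,0,1,1,0,1,1,0,0,0,0,0,0,0
80,Stares blankly,AttentionProblems,0,0,0,0,0,0,1,1,1,0,0,0,0,0
81,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
82,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
83,Stores up too many things he/she does not need,ThoughtProblems,0,1,0,1,1,0,0,0,1,0,0,0,0,0
84,Strange behavior,ThoughtProblems,0,1,0,1,1,1,1,1,1,0,0,0,0,0
85,Strange ideas,ThoughtProblems,0,1,0,1,1,0,0,0,1,0,0,0,0,0
86,"Stubborn, sullen, or irritable",AggressiveBehavior,0,0,0,0,0,0,0,0,1,0,0,0,1,0
87,Sudden changes in mood or feelings,AggressiveBehavior,0,0,0,0,0,0,0,0,1,0,0,0,0,0
88,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
89,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
90,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
91,,none,0,0,0,0,0,0,0,0,0,1,0,0,0,0
92,Talks or walks in sleep,ThoughtProblems,0,1,0,1,1,0,0,0,0,0,0,0,0,0
93,,none,0,0,0,0,0,0,0,0,0,0,0,1,0,0
94,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
95,Temper tantrums or hot temper,AggressiveBehavior,0,0,0,0,0,0,0,0,1,0,0,0,1,0
96,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
97,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
98,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
99,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
100,Trouble sleeping,ThoughtProblems,0,1,0,1,1,0,0,0,0,1,0,0,0,0
101,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
102,"Underactive, slow moving, or lacks energy",WithdrawnDepressed,1,0,0,1,1,0,0,1,0,1,0,0,0,0
103,"Unhappy, sad, or depressed",WithdrawnDepressed,1,0,0,1,1,0,0,0,0,1,0,0,0,0
104,,none,0,0,0,0,0,0,0,0,0,0,0,1,0,0
105,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
106,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,1
107,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
108,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
109,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
110,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
111,"Withdrawn, doesn't get involved with others",WithdrawnDepressed,1,0,0,1,1,1,1,1,1,0,0,0,0,0
112,,none,0,0,0,0,0,0,0,0,0,0,1,0,0,0
113,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
114,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
115,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
116,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
117,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
118,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
119,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
120,,none,0,0,0,0,0,0,0,0,0,0,0,0,0,0
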