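title,expert_score,q_rand,q_plus,q_minus,phi,search_rank,lsa_value
How to promote your website online (for free!),9.5,0.36,0.10,0.15,0.43,3,0.96
How to promote your website: tips for digital domination,9.1,0.27,0.03,0.04,0.42,1,0.99
How to promote your blog,8.3,0.17,0.07,0.16,0.25,7,0.93
7 Best techniques to promote your website for free,7.3,0.14,0,0,0.12,2,0.99
33 Creative ways to promote your app for free,6.6,0.19,0.07,0.12,0.32,5,0.95
Content promotion: how to balance organic results with paid ads,6.5,0.34,0.14,0.32,0.31,4,0.84
10 Social-media marketing strategies for companies,6.4,0.23,0,0,0.20,9,0.56
The 11 golden rules of writing content for your website,5.8,0.085,0.04,0.08,0.26,8,0.68
Promotion (marketing) (Wikipedia article),5.6,0.04,0,0,0.04,6,0.52
6 Free analytics tools to help you understand your competitor's web traffic,4.8,0,0,0,,10,0
27 of the best website designs to inspire you in 2020,4.4,0.07,0,0,0.38,14,0.83
Internet branding (Wikipedia article),4.1,0.23,0.09,0.21,0.23,12,0.76
How to start your own brand from scratch in 7 steps,3.9,0,0,0,,11,0
Website (Wikipedia article),3.0,0.02,0,0,0.05,13,0.51
The new age of content Darwinism (and how to apply it),1.9,0,0,0,,15,0
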