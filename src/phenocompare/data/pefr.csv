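subject,method,replicate,value
1,wright,1,494
1,wright,2,490
1,mini,1,512
1,mini,2,525
2,wright,1,395
2,wright,2,397
2,mini,1,430
2,mini,2,415
3,wright,1,516
3,wright,2,512
3,mini,1,520
3,mini,2,508
4,wright,1,434
4,wright,2,401
4,mini,1,428
4,mini,2,444
5,wright,1,476
5,wright,2,470
5,mini,1,500
5,mini,2,500
6,wright,1,557
6,wright,2,611
6,mini,1,600
6,mini,2,625
7,wright,1,413
7,wright,2,415
7,mini,1,364
7,mini,2,460
8,wright,1,442
8,wright,2,431
8,mini,1,380
8,mini,2,390
9,wright,1,650
9,wright,2,638
9,mini,1,658
9,mini,2,642
10,wright,1,433
10,wright,2,429
10,mini,1,445
10,mini,2,432
11,wright,1,417
11,wright,2,420
11,mini,1,432
11,mini,2,420
12,wright,1,656
12,wright,2,633
12,mini,1,626
12,mini,2,605
13,wright,1,267
13,wright,2,275
13,mini,1,260
13,mini,2,227
14,wright,1,478
14,wright,2,492
14,mini,1,477
14,mini,2,467
15,wright,1,178
15,wright,2,165
15,mini,1,259
15,mini,2,268
16,wright,1,423
16,wright,2,372
16,mini,1,350
16,mini,2,370
17,wright,1,427
17,wright,2,421
17,mini,1,451
17,mini,2,443
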